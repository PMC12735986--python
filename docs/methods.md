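# Methods

## Model and assumptions

The odorant is reduced to its two frontier orbitals — a HOMO at εH and
a LUMO at εL, hybridized by an electronic coupling J — with no receptor
electronic states included.  Tunneling through the molecule is treated
as an evanescent-wave coupling problem: the two-level system is
continued as an infinite diatomic tight-binding chain with alternating
on-site energies (εH, εL) and uniform intra- and inter-cell hopping J.
This is the minimal periodic embedding whose band edges sit exactly at
εH and εL, so the chain's forbidden gap equals the molecular gap Δ.
Working in the zero-bias, coherent-tunneling limit, the terminals drop
out and transmission attenuates as τ = exp(−2βL) with a unit prefactor:
τ is a bare attenuation factor in (0, 1], not an absolute conductance.

Within the gap the unit-cell transfer matrix — the product of the
single-site matrices [[(E−ε)/J, −1], [1, 0]] for ε = εH then εL — has
determinant 1 and trace (E−εH)(E−εL)/J² − 2 = −2·cosh(βa), so its
eigenvalues are −e^(±βa) and

    β(E) = (2/a)·arcsinh( √((Δ/2)² − (E−μ)²) / 2J ).

β vanishes at the band edges, is symmetric about midgap μ, and has a
unique stationary point dβ/dE = 0 at E = μ where
β_bp = (2/a)·arcsinh(Δ/4J).  Note that in this single-loop two-band
model the stationary point is the *maximum* of β among in-gap energies;
the off-midgap "indirect" channel at E = εH + Δ/6 (εL/6 in the εH = 0
reference) therefore always carries a slightly smaller decay rate.  We
implement the literal stationary-point condition and surface both
channels rather than reinterpreting either as globally optimal.  The
indirect channel is evaluated at that single energy; no averaging over
the interval below it is performed.

A transfer matrix can be written with either site ordering of the
two-component amplitude vector; the orderings are similarity-related
and share the eigenvalue spectrum, so the package uses the standard
site-ordered cell matrix throughout.

## Parameters, units, defaults

All energies are in eV, lengths in Å, masses in amu; the only conversion
constants are ℏ²/2mₑ = 3.8099821 eV·Å² and 1 amu = 1822.888486 mₑ
(`odortunnel.constants`).

- **εH = 0** is the default energy reference; any reference is accepted
  since every formula uses differences.
- **a = 1 Å** unit-cell length by default.  β is reported per Å and the
  printed decay-rate spans of odorant-scale (Δ, J) grids (≈0.33–4.62 Å⁻¹
  over Δ ∈ [2, 10] eV × J ∈ [0.5, 3] eV) arise with this choice; a is
  configurable and recorded in all outputs.
- **Weak-mixing validity**: the two-level picture presumes distinct
  HOMO/LUMO, flagged as J < 1 eV and J < Δ with *strict* inequalities
  (the J = 1 eV boundary is flagged invalid).
- **Detectability floor** τ_floor = 1e-8, the practical noise floor of
  single-molecule junction experiments; configurable.
- **Regime boundary**: β < 0.5 Å⁻¹ (strict) labels near-resonant
  transport; the boundary itself is off-resonant.
- **Barrier height** Φ = E + ℏ²β²/2mₑ uses the bare electron mass; no
  effective-mass option.
- **Vibronic defaults**: the mode preset M = 8.25 amu, ℏω = 0.2 eV
  ("Brookes defaults", representative of odorant vibrations; force
  constant Mω² = 78.94 eV/Å²).  The Slater–Koster fall-off η = 2.0 and
  equilibrium distance a0 = 1.4 Å are not measured quantities; they are
  a typical π-conjugated carbon-bond scale, fully configurable, and
  echoed into every output.  Displacement u is the instantaneous
  inter-site distance, so u = a0 is equilibrium.  α is reported as a
  magnitude (the sign of dJ/du is a mode phase convention), and only
  the linear/quadratic shapes of α(J0), λ(J0) and the magnitude regime
  of λ are meaningful — the absolute α scale inherits the (η, a0)
  choice.
- **Default sweep grid**: Δ ∈ [2, 10] eV spans conjugated to saturated
  odorant gaps; J ∈ [0.5, 3] eV spans weakly localized to strongly
  hybridized frontier orbitals; 51×51 points complete in well under a
  second.

## Numerical choices

- The closed-form β is the production path.  The transfer-matrix
  eigenvalue route (β = ln|λ_max|/a) is kept as an internal cross-check
  and as the objective of the branch-point search.
- The branch point is located by Brent root-finding on a central
  difference of the eigenvalue-route β (step 1e-7·Δ, tolerance 1e-12 on
  E), with the arcsinh closed form as the convergence certificate in
  the tests.
- Out-of-gap energies raise a domain error: there |trace| ≤ 2 and the
  modes are propagating, so no decay rate exists.
- The finite-chain oracle computes the end-to-end resolvent element of
  open diatomic chains, G_{1,n} = J^(n−1)/det(E−H), via the ratio form
  of the tridiagonal determinant recursion with accumulated
  log-magnitudes (no under/overflow at any chain length).  A 1e-12 eV
  imaginary energy shift regularizes exact eigenvalue collisions, which
  cannot occur in-gap but are guarded against anyway.  β is the
  least-squares slope of −log|G| against chain length.  When no chain
  window is supplied the oracle adapts: starting from 4–16 cells, it
  pushes the window to longer chains using its own slope estimate until
  the shortest chain attenuates by at least e⁻⁵, since slowly decaying
  states (small β) carry a finite-size tail that biases short-chain
  slopes.
- The coupling threshold J_min(Δ, L, τ_min) is the closed-form
  inversion J_min = Δ/(4·sinh(β_req·a/2)), β_req = −ln(τ_min)/2L, with
  a bisection-on-J route retained as a cross-check.  J_min is
  *increasing* in τ_min: demanding more transmission requires stronger
  coupling, while lowering the floor relaxes it.  τ_min outside (0, 1)
  has no finite threshold and is rejected.
- Grid exports write floats with 17 significant digits, so round-trips
  are exact to float precision and byte-identical for identical
  configs; the JSON sidecar carries a SHA-256 hash of the canonical
  config encoding for provenance.

## What the random fixtures emulate

The fixture generator draws odorants with gaps uniform in [0.5, 12] eV
and couplings uniform in [0.05, 3] eV (the physically motivated spans
above, padded at both ends), with probe energies uniform inside the gap
but kept 2% off the band edges where β → 0 and any relative comparison
degenerates.  These ensembles exercise the algebraic identities and the
three-route equivalence of β; they are parameter sweeps of an analytic
model, not simulations of real molecules — passing tests certify the
internal consistency and the stated regime claims of the model, not the
accuracy of (Δ, J) assignments for any particular odorant, which must
come from experiment or quantum chemistry.

## Known limitations

- Two bands only: a single evanescent loop, no multi-branch complex
  band structures, and no explicit electrode self-energies.
- No absolute conductance, bias or temperature dependence; τ is an
  attenuation factor.
- The vibronic layer is single-mode, harmonic, frozen-phonon, and stops
  at the reorganization energy; full Marcus rates (driving force,
  temperature) and inelastic spectra are out of scope.
- HOMO/LUMO values are inputs; no quantum-chemistry file readers.
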