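"""Physical constants and unit conversions.

The package works in a fixed unit system throughout: energies in eV,
lengths in Å, masses in amu.  Everything needed to move between these
and SI reduces to the two constants below (CODATA 2018).
"""

#: ℏ²/(2mₑ) in eV·Å² — kinetic-energy prefactor for a bare electron.
HBAR2_OVER_2ME = 3.8099821161548593

#: One atomic mass unit expressed in electron masses.
AMU_TO_ME = 1822.888486209


def force_constant(mass_amu: float, hbar_omega_ev: float) -> float:
    """Harmonic force constant M·ω² in eV/Å².

    For a mode of effective mass ``mass_amu`` (amu) and vibrational
    quantum ``hbar_omega_ev`` = ℏω (eV),

        M·ω² = M (ℏω)² / ℏ² = mass_amu · AMU_TO_ME · (ℏω)² / (2·ℏ²/2mₑ)
    """
    return mass_amu * AMU_TO_ME * hbar_omega_ev**2 / (2.0 * HBAR2_OVER_2ME)
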