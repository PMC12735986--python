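"""Two-level electronic model of an odorant molecule.

An odorant is reduced to its frontier orbitals: a HOMO level at εH, a
LUMO level at εL, and an electronic coupling J hybridizing them,

    H = εH c†H cH + εL c†L cL + J (c†H cL + c†L cH).

The gap Δ = εL − εH and the coupling J are the intrinsic energy scales
that control everything downstream (gap states, tunneling, vibronics).
By convention εH = 0 is used as the energy reference, but all formulas
depend only on differences, so any reference is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterValidationError

__all__ = [
    "TwoLevelOdorant",
    "WeakMixingCheck",
    "make_odorant",
    "eigenvalues",
    "mixing_angle",
    "check_weak_mixing",
]


@dataclass(frozen=True)
class TwoLevelOdorant:
    """Frontier-orbital description of an odorant.

    Parameters
    ----------
    eps_H, eps_L : float
        HOMO and LUMO on-site energies in eV; ``eps_L > eps_H`` is
        required so the gap is strictly positive.
    J : float
        Electronic coupling between the two levels in eV; must be > 0.
    name : str, optional
        Label carried through reports.
    """

    eps_H: float
    eps_L: float
    J: float
    name: str | None = None

    def __post_init__(self):
        if not math.isfinite(self.eps_H) or not math.isfinite(self.eps_L):
            raise ParameterValidationError("eps_H/eps_L", "level energies must be finite")
        if self.eps_L <= self.eps_H:
            raise ParameterValidationError(
                "eps_L", f"gap must be positive: eps_L={self.eps_L} <= eps_H={self.eps_H}"
            )
        if not (self.J > 0) or not math.isfinite(self.J):
            raise ParameterValidationError("J", f"electronic coupling must be positive, got {self.J}")

    @property
    def delta(self) -> float:
        """Energy gap Δ = εL − εH (eV)."""
        return self.eps_L - self.eps_H

    @property
    def midgap(self) -> float:
        """Midgap energy μ = (εH + εL)/2 (eV)."""
        return 0.5 * (self.eps_H + self.eps_L)


@dataclass(frozen=True)
class WeakMixingCheck:
    """Outcome of the weak-mixing validity check; truthy iff satisfied."""

    ok: bool
    coupling_below_1ev: bool
    coupling_below_gap: bool
    message: str

    def __bool__(self) -> bool:
        return self.ok


def make_odorant(
    eps_H: float, eps_L: float, J: float, name: str | None = None
) -> TwoLevelOdorant:
    """Construct and validate a two-level odorant model."""
    return TwoLevelOdorant(eps_H=eps_H, eps_L=eps_L, J=J, name=name)


def eigenvalues(odorant: TwoLevelOdorant) -> tuple[float, float]:
    """Hybridized level energies (E−, E+) of the 2×2 Hamiltonian.

    Closed form E∓ = μ ∓ sqrt((Δ/2)² + J²).  Level repulsion pushes
    E− below the HOMO and E+ above the LUMO for any J > 0.
    """
    half = math.hypot(0.5 * odorant.delta, odorant.J)
    mu = odorant.midgap
    return (mu - half, mu + half)


def mixing_angle(odorant: TwoLevelOdorant) -> float:
    """HOMO–LUMO mixing angle θ = ½·arctan(2J/Δ) in radians.

    θ ∈ (0, π/4): small when the levels stay distinct, π/4 in the
    degenerate (symmetric-dimer) limit Δ → 0.
    """
    return 0.5 * math.atan2(2.0 * odorant.J, odorant.delta)


def check_weak_mixing(odorant: TwoLevelOdorant) -> WeakMixingCheck:
    """Check the weak-mixing validity condition of the two-level picture.

    The two-level description of tunneling presumes the HOMO and LUMO
    remain distinct rather than strongly hybridized, which holds when
    J < 1 eV and J < Δ (both strict).  Both sub-conditions are reported
    separately in the diagnostic message.
    """
    below_1ev = odorant.J < 1.0
    below_gap = odorant.J < odorant.delta
    ok = below_1ev and below_gap
    theta = mixing_angle(odorant)
    message = (
        f"J={odorant.J:g} eV "
        f"{'<' if below_1ev else '>='} 1 eV; "
        f"J {'<' if below_gap else '>='} Δ={odorant.delta:g} eV; "
        f"mixing angle θ={theta:.4f} rad; "
        f"weak mixing {'satisfied' if ok else 'violated'}"
    )
    return WeakMixingCheck(ok, below_1ev, below_gap, message)
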