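"""Frozen-phonon vibronic model: distance-dependent coupling, α and λ.

The odorant is treated as an oscillating dimer whose electronic coupling
depends exponentially on the inter-site distance u,

    J(u) = J0 · exp(−η·(u/a0 − 1)),

a two-center Slater–Koster form well suited to π-conjugated systems.
In the frozen-phonon regime the linear electron–phonon coupling is the
derivative α = |dJ/du| at equilibrium, α = η·J0/a0 — linear in J0.  With
a harmonic mode V(u) = ½·Mω²·u², displacing the potential minimum by the
linear coupling yields the Marcus reorganization energy

    λ = α² / (2·Mω²),

quadratic in J0.  The mode parameters M = 8.25 amu and ℏω = 0.2 eV are
packaged as the "Brookes defaults" preset, representative of odorant
molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import force_constant
from .errors import ParameterValidationError

__all__ = [
    "VibronicModel",
    "brookes_defaults",
    "coupling_at_displacement",
    "linear_eph_coupling",
    "harmonic_potential",
    "reorganization_energy",
]

#: Brookes-preset effective mass (amu) and phonon quantum (eV).
BROOKES_MASS_AMU = 8.25
BROOKES_HBAR_OMEGA_EV = 0.2

#: Slater–Koster fall-off rate and equilibrium distance defaults; not
#: measured quantities — a typical π-conjugated carbon-bond scale.
DEFAULT_ETA = 2.0
DEFAULT_A0 = 1.4


@dataclass(frozen=True)
class VibronicModel:
    """Exponential-coupling vibronic parameters.

    Parameters
    ----------
    J0 : float
        Equilibrium electronic coupling (eV), ≥ 0.
    eta : float
        Dimensionless fall-off rate of the exponential coupling law.
    a0 : float
        Equilibrium inter-site distance (Å).
    M : float
        Effective mode mass (amu).
    hbar_omega : float
        Phonon quantum ℏω (eV).
    """

    J0: float
    eta: float = DEFAULT_ETA
    a0: float = DEFAULT_A0
    M: float = BROOKES_MASS_AMU
    hbar_omega: float = BROOKES_HBAR_OMEGA_EV

    def __post_init__(self):
        if self.J0 < 0:
            raise ParameterValidationError("J0", f"equilibrium coupling must be >= 0, got {self.J0}")
        for name in ("eta", "a0", "M", "hbar_omega"):
            if not (getattr(self, name) > 0):
                raise ParameterValidationError(name, f"must be positive, got {getattr(self, name)}")

    @property
    def force_constant(self) -> float:
        """Mω² in eV/Å²."""
        return force_constant(self.M, self.hbar_omega)


def brookes_defaults(J0: float, eta: float = DEFAULT_ETA, a0: float = DEFAULT_A0) -> VibronicModel:
    """Vibronic model with the Brookes mode preset (M = 8.25 amu, ℏω = 0.2 eV)."""
    return VibronicModel(J0=J0, eta=eta, a0=a0)


def coupling_at_displacement(model: VibronicModel, u: float) -> float:
    """Electronic coupling J(u) = J0·exp(−η·(u/a0 − 1)) at inter-site distance u (Å).

    ``u`` is the instantaneous inter-site distance, so u = a0 recovers J0.
    """
    if not (u > 0):
        raise ParameterValidationError("u", f"inter-site distance must be positive, got {u}")
    return model.J0 * math.exp(-model.eta * (u / model.a0 - 1.0))


def linear_eph_coupling(model: VibronicModel) -> float:
    """Linear electron–phonon coupling α = |dJ/du| at u = a0, in eV/Å.

    Equals η·J0/a0 — linear in J0.  Reported as a magnitude; the sign of
    dJ/du is a phase convention for the mode.
    """
    return model.eta * model.J0 / model.a0


def harmonic_potential(model: VibronicModel, u: float) -> float:
    """Harmonic mode energy V(u) = ½·Mω²·u² in eV (u in Å)."""
    return 0.5 * model.force_constant * u**2


def reorganization_energy(model: VibronicModel) -> float:
    """Marcus reorganization energy λ = α²/(2·Mω²) in eV; quadratic in J0."""
    alpha = linear_eph_coupling(model)
    return alpha**2 / (2.0 * model.force_constant)
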