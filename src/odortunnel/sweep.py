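"""Parameter sweeps, odorant screening, fixtures and serialization.

Regenerates the model's two headline maps: decay-rate grids over the
(Δ, J) plane for the direct (branch-point) and indirect (near-HOMO)
channels, and the vibronic curves α(J0), λ(J0).  Grids are exported as
long-format CSV with a JSON metadata sidecar carrying a config hash for
provenance; exports round-trip losslessly to float precision and are
byte-deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterValidationError
from .gap_states import branch_point_beta, indirect_beta
from .model_core import TwoLevelOdorant, make_odorant
from .transport import (
    DEFAULT_TAU_FLOOR,
    barrier_height,
    classify_regime,
    transmission,
)
from .vibronic import DEFAULT_A0, DEFAULT_ETA, VibronicModel, linear_eph_coupling, reorganization_energy

__all__ = [
    "SweepConfig",
    "SweepGrid",
    "OdorantRecord",
    "REFERENCE_ODORANTS",
    "run_decay_sweep",
    "run_vibronic_sweep",
    "screen_odorants",
    "export_grid",
    "load_grid",
    "generate_fixtures",
    "FixtureCase",
]

logger = logging.getLogger(__name__)

#: In-text reference gaps of common odorants (eV).
REFERENCE_ODORANTS: tuple["OdorantRecord", ...]


@dataclass(frozen=True)
class SweepConfig:
    """Axes and conventions of a (Δ, J) decay-rate sweep.

    Default axes Δ ∈ [2, 10] eV × J ∈ [0.5, 3] eV span conjugated to
    saturated odorant gaps and weakly localized to strongly hybridized
    frontier orbitals; with a = 1 Å this reproduces the characteristic
    decay-rate span from about 0.3 to about 4.6 Å⁻¹.
    """

    delta_range: tuple[float, float, int] = (2.0, 10.0, 51)
    j_range: tuple[float, float, int] = (0.5, 3.0, 51)
    a: float = 1.0
    L: float = 10.0
    tau_floor: float = DEFAULT_TAU_FLOOR
    vibronic_eta: float = DEFAULT_ETA
    vibronic_a0: float = DEFAULT_A0
    j0_range: tuple[float, float, int] = (0.02, 1.0, 50)
    seed: int = 0

    def __post_init__(self):
        for name in ("delta_range", "j_range", "j0_range"):
            lo, hi, n = getattr(self, name)
            if not (lo < hi):
                raise ParameterValidationError(name, f"min must be < max, got ({lo}, {hi})")
            if n < 2:
                raise ParameterValidationError(name, f"need at least 2 grid points, got {n}")
            if not (lo > 0) and name != "delta_range":
                raise ParameterValidationError(name, f"couplings must be positive, got min {lo}")
        if not (self.delta_range[0] > 0):
            raise ParameterValidationError("delta_range", "gaps must be positive")
        for name in ("a", "L"):
            if not (getattr(self, name) > 0):
                raise ParameterValidationError(name, f"must be positive, got {getattr(self, name)}")
        if not (0 < self.tau_floor < 1):
            raise ParameterValidationError("tau_floor", f"must lie in (0, 1), got {self.tau_floor}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON encoding of the config."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass(frozen=True)
class SweepGrid:
    """Decay-rate grids over the (Δ, J) plane with transport annotations.

    Rows index the gap axis, columns the coupling axis.
    """

    delta_axis: np.ndarray
    j_axis: np.ndarray
    beta_direct: np.ndarray
    beta_indirect: np.ndarray
    tau_direct: np.ndarray
    weak_mixing_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = (len(self.delta_axis), len(self.j_axis))
        for name in ("beta_direct", "beta_indirect", "tau_direct", "weak_mixing_mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ParameterValidationError(name, f"shape {arr.shape} != axes shape {shape}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (Δ, J) grid point."""
        dg, jg = np.meshgrid(self.delta_axis, self.j_axis, indexing="ij")
        return pd.DataFrame(
            {
                "delta_eV": dg.ravel(),
                "J_eV": jg.ravel(),
                "beta_direct_inv_A": self.beta_direct.ravel(),
                "beta_indirect_inv_A": self.beta_indirect.ravel(),
                "tau_direct": self.tau_direct.ravel(),
                "weak_mixing": self.weak_mixing_mask.ravel(),
            }
        )


@dataclass(frozen=True)
class OdorantRecord:
    """A named odorant reduced to its HOMO–LUMO gap."""

    name: str
    delta: float
    note: str = ""

    def __post_init__(self):
        if not (self.delta > 0):
            raise ParameterValidationError("delta", f"gap must be positive, got {self.delta}")


REFERENCE_ODORANTS = (
    OdorantRecord("vanillin", 5.0, "conjugated aromatic; ~5 eV gap"),
    OdorantRecord("menthol", 7.0, "saturated terpenoid; ~7 eV gap"),
    OdorantRecord("hydrogen sulfide", 8.0, "small inorganic; ~8 eV gap"),
)


def run_decay_sweep(config: SweepConfig | None = None) -> SweepGrid:
    """Fill direct/indirect decay-rate grids over the configured (Δ, J) plane.

    Per grid point: branch-point and indirect-channel decay rates,
    the direct-channel transmission at the configured length, and the
    weak-mixing validity flag (J < 1 eV and J < Δ).  Deterministic for a
    fixed config.
    """
    config = config or SweepConfig()
    t0 = time.perf_counter()
    delta = np.linspace(*config.delta_range)
    j = np.linspace(*config.j_range)
    dg, jg = np.meshgrid(delta, j, indexing="ij")
    beta_d = branch_point_beta(dg, jg, config.a)
    beta_i = indirect_beta(dg, jg, config.a)
    tau = np.exp(-2.0 * beta_d * config.L)
    weak = (jg < 1.0) & (jg < dg)
    grid = SweepGrid(
        delta_axis=delta,
        j_axis=j,
        beta_direct=beta_d,
        beta_indirect=beta_i,
        tau_direct=tau,
        weak_mixing_mask=weak,
        metadata={
            "a_A": config.a,
            "L_A": config.L,
            "tau_floor": config.tau_floor,
            "prefactor": 1.0,
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
        },
    )
    logger.info(
        "decay sweep: Δ∈[%g,%g]x%d eV, J∈[%g,%g]x%d eV, a=%g Å, L=%g Å, "
        "τ prefactor=1, floor=%g; %.3f s",
        *config.delta_range, *config.j_range, config.a, config.L,
        config.tau_floor, time.perf_counter() - t0,
    )
    return grid


def run_vibronic_sweep(config: SweepConfig | None = None) -> pd.DataFrame:
    """Vibronic curves α(J0) and λ(J0) over the configured J0 axis.

    The axis is confined to (0, 1] eV by default, where the two-level
    picture remains valid; α is exactly linear and λ exactly quadratic
    in J0.
    """
    config = config or SweepConfig()
    j0 = np.linspace(*config.j0_range)
    if j0.size == 0:
        raise ParameterValidationError("j0_range", "empty coupling axis")
    rows = []
    for j0_val in j0:
        model = VibronicModel(J0=float(j0_val), eta=config.vibronic_eta, a0=config.vibronic_a0)
        rows.append(
            {
                "J0_eV": float(j0_val),
                "alpha_eV_per_A": linear_eph_coupling(model),
                "lambda_eV": reorganization_energy(model),
            }
        )
    return pd.DataFrame(rows)


def screen_odorants(
    records: Sequence[OdorantRecord],
    J: float,
    L: float = 10.0,
    a: float = 1.0,
    tau_floor: float = DEFAULT_TAU_FLOOR,
) -> pd.DataFrame:
    """Transport report for a set of reference odorants at coupling J.

    Each odorant is placed in the εH = 0 reference with its tabulated
    gap; the report carries both channel decay rates, the transmission
    across L, the branch-point barrier height, the regime label and a
    detectability flag.
    """
    rows = []
    for rec in records:
        odorant = make_odorant(0.0, rec.delta, J, name=rec.name)
        beta_d = float(branch_point_beta(rec.delta, J, a))
        beta_i = float(indirect_beta(rec.delta, J, a))
        tau = transmission(beta_d, L)
        rows.append(
            {
                "name": rec.name,
                "delta_eV": rec.delta,
                "J_eV": J,
                "beta_direct_inv_A": beta_d,
                "beta_indirect_inv_A": beta_i,
                "tau": tau,
                "phi_eV": barrier_height(odorant.midgap, beta_d),
                "regime": classify_regime(beta_d),
                "measurable": tau >= tau_floor,
            }
        )
    columns = [
        "name", "delta_eV", "J_eV", "beta_direct_inv_A", "beta_indirect_inv_A",
        "tau", "phi_eV", "regime", "measurable",
    ]
    return pd.DataFrame(rows, columns=columns)


def export_grid(grid: SweepGrid, out_dir: str | Path, stem: str = "decay_sweep", plot: bool = False) -> dict:
    """Write a sweep grid as CSV + JSON sidecar (optionally heatmap PNGs).

    Floats are written with 17 significant digits so a re-import
    reproduces the arrays to ≤1e-12; output is byte-identical for
    identical configs.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        json_path = out_dir / f"{stem}.json"
        grid.to_frame().to_csv(csv_path, index=False, float_format="%.17g", lineterminator="\n")
        json_path.write_text(json.dumps(grid.metadata, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write sweep outputs under {out_dir}: {exc}") from exc
    paths = {"csv": csv_path, "json": json_path}
    if plot:
        paths["png"] = _plot_grid(grid, out_dir / f"{stem}.png")
    return paths


def _plot_grid(grid: SweepGrid, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), constrained_layout=True)
    for ax, arr, title in (
        (axes[0], grid.beta_direct, "direct (branch point)"),
        (axes[1], grid.beta_indirect, "indirect (near-HOMO)"),
    ):
        im = ax.pcolormesh(grid.j_axis, grid.delta_axis, arr, shading="auto")
        ax.set_xlabel("J (eV)")
        ax.set_ylabel("Δ (eV)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="β (Å⁻¹)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def load_grid(out_dir: str | Path, stem: str = "decay_sweep") -> SweepGrid:
    """Re-assemble a :class:`SweepGrid` from an exported CSV + sidecar."""
    out_dir = Path(out_dir)
    frame = pd.read_csv(out_dir / f"{stem}.csv")
    metadata = json.loads((out_dir / f"{stem}.json").read_text())
    delta = np.unique(frame["delta_eV"].to_numpy())
    j = np.unique(frame["J_eV"].to_numpy())
    shape = (len(delta), len(j))
    return SweepGrid(
        delta_axis=delta,
        j_axis=j,
        beta_direct=frame["beta_direct_inv_A"].to_numpy().reshape(shape),
        beta_indirect=frame["beta_indirect_inv_A"].to_numpy().reshape(shape),
        tau_direct=frame["tau_direct"].to_numpy().reshape(shape),
        weak_mixing_mask=frame["weak_mixing"].to_numpy().reshape(shape),
        metadata=metadata,
    )


class FixtureCase(NamedTuple):
    """A random odorant with one in-gap probe energy."""

    odorant: TwoLevelOdorant
    energy: float


def generate_fixtures(seed: int, n: int) -> list[FixtureCase]:
    """Reproducible random ensemble of odorants with in-gap energies.

    Gaps uniform in [0.5, 12] eV, couplings uniform in [0.05, 3] eV
    (εH = 0 reference), probe energies uniform strictly inside the gap.
    Identical seeds yield identical ensembles.
    """
    if n < 1:
        raise ParameterValidationError("n", f"need at least one fixture, got {n}")
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        delta = rng.uniform(0.5, 12.0)
        J = rng.uniform(0.05, 3.0)
        # keep probes safely off the band edges where β → 0
        energy = delta * rng.uniform(0.02, 0.98)
        cases.append(FixtureCase(make_odorant(0.0, delta, J), energy))
    return cases
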