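"""Sweep engine: grids, exports, screening, fixtures."""

import numpy as np
import pandas as pd
import pytest

from odortunnel import (
    ParameterValidationError,
    REFERENCE_ODORANTS,
    SweepConfig,
    coupling_threshold,
    export_grid,
    generate_fixtures,
    load_grid,
    run_decay_sweep,
    run_vibronic_sweep,
    screen_odorants,
)


@pytest.fixture(scope="module")
def default_grid():
    return run_decay_sweep(SweepConfig())


class TestDecaySweep:
    def test_span_matches_corner_values(self, default_grid):
        g = default_grid
        i_max, j_max = np.unravel_index(np.argmax(g.beta_direct), g.beta_direct.shape)
        assert (g.delta_axis[i_max], g.j_axis[j_max]) == (10.0, 0.5)
        assert g.beta_direct.max() == pytest.approx(4.624876682545505, rel=1e-12)
        i_min, j_min = np.unravel_index(np.argmin(g.beta_direct), g.beta_direct.shape)
        assert (g.delta_axis[i_min], g.j_axis[j_min]) == (2.0, 3.0)
        assert g.beta_direct.min() == pytest.approx(0.3318091005386023, rel=1e-12)

    def test_channel_ordering_and_monotone_structure(self, default_grid):
        g = default_grid
        assert np.all(g.beta_indirect < g.beta_direct)
        assert np.all(g.beta_direct >= 0)
        assert np.all(np.diff(g.beta_direct, axis=1) < 0)  # decreasing in J
        assert np.all(np.diff(g.beta_direct, axis=0) > 0)  # increasing in gap

    def test_transmission_grid_is_exact_exponential(self, default_grid):
        g = default_grid
        np.testing.assert_array_equal(g.tau_direct, np.exp(-2.0 * g.beta_direct * g.metadata["L_A"]))

    def test_weak_mixing_mask(self, default_grid):
        g = default_grid
        dg, jg = np.meshgrid(g.delta_axis, g.j_axis, indexing="ij")
        np.testing.assert_array_equal(g.weak_mixing_mask, (jg < 1.0) & (jg < dg))

    def test_determinism(self):
        cfg = SweepConfig(delta_range=(3.0, 3.5, 2), j_range=(1.0, 1.5, 2))
        g1, g2 = run_decay_sweep(cfg), run_decay_sweep(cfg)
        np.testing.assert_array_equal(g1.beta_direct, g2.beta_direct)
        assert g1.metadata["config_hash"] == g2.metadata["config_hash"]


class TestExport:
    def test_round_trip_and_sidecar(self, tmp_path):
        cfg = SweepConfig(delta_range=(2.0, 9.0, 7), j_range=(0.5, 2.5, 5))
        grid = run_decay_sweep(cfg)
        paths = export_grid(grid, tmp_path)
        frame = pd.read_csv(paths["csv"])
        assert len(frame) == 7 * 5
        back = load_grid(tmp_path)
        for name in ("beta_direct", "beta_indirect", "tau_direct"):
            np.testing.assert_allclose(getattr(back, name), getattr(grid, name), rtol=1e-12, atol=0)
        assert back.metadata["config_hash"] == cfg.config_hash()

    def test_byte_identical_outputs_for_identical_config(self, tmp_path):
        cfg = SweepConfig(delta_range=(2.0, 6.0, 4), j_range=(0.5, 1.5, 3))
        p1 = export_grid(run_decay_sweep(cfg), tmp_path / "a")
        p2 = export_grid(run_decay_sweep(cfg), tmp_path / "b")
        assert p1["csv"].read_bytes() == p2["csv"].read_bytes()
        assert p1["json"].read_bytes() == p2["json"].read_bytes()

    def test_unwritable_path_raises_with_path_named(self, tmp_path):
        target = tmp_path / "blocked"
        target.write_text("a file, not a directory\n")
        with pytest.raises(OSError, match="blocked"):
            export_grid(run_decay_sweep(SweepConfig(delta_range=(2, 3, 2), j_range=(1, 2, 2))), target)


class TestVibronicSweep:
    def test_shape_laws_rowwise(self):
        table = run_vibronic_sweep(SweepConfig())
        j0 = table["J0_eV"].to_numpy()
        alpha = table["alpha_eV_per_A"].to_numpy()
        lam = table["lambda_eV"].to_numpy()
        np.testing.assert_allclose(alpha / j0, alpha[0] / j0[0], rtol=1e-12)
        np.testing.assert_allclose(lam / j0**2, lam[0] / j0[0] ** 2, rtol=1e-12)
        assert np.all(np.diff(alpha) > 0) and np.all(np.diff(lam) > 0)

    def test_endpoint_matches_vibronic_module(self):
        table = run_vibronic_sweep(SweepConfig())
        last = table.iloc[-1]
        assert last["J0_eV"] == 1.0
        assert last["alpha_eV_per_A"] == pytest.approx(1.4285714285714286, rel=1e-12)
        assert last["lambda_eV"] == pytest.approx(0.012925662602468498, rel=1e-10)

    def test_empty_axis_rejected(self):
        with pytest.raises(ParameterValidationError):
            SweepConfig(j0_range=(0.5, 0.5, 2))


class TestScreening:
    def test_vanillin_is_a_poor_tunneling_conductor(self):
        report = screen_odorants(REFERENCE_ODORANTS, J=1.0, L=10.0)
        vanillin = report.set_index("name").loc["vanillin"]
        assert vanillin["tau"] == pytest.approx(6.3306e-19, rel=1e-4)
        assert not vanillin["measurable"]
        assert vanillin["regime"] == "off_resonant"
        assert report["beta_indirect_inv_A"].lt(report["beta_direct_inv_A"]).all()

    def test_threshold_coupling_sits_at_detectability_boundary(self):
        j_min = coupling_threshold(5.0, 10.0, 1e-8)
        report = screen_odorants(REFERENCE_ODORANTS[:1], J=j_min, L=10.0)
        assert report.loc[0, "tau"] == pytest.approx(1e-8, rel=1e-9)

    def test_empty_records_give_empty_report(self):
        report = screen_odorants([], J=1.0)
        assert report.empty
        assert "beta_direct_inv_A" in report.columns


class TestFixtures:
    def test_reproducible_and_valid(self):
        a = generate_fixtures(seed=7, n=25)
        b = generate_fixtures(seed=7, n=25)
        assert a == b
        for case in a:
            o = case.odorant
            assert 0.5 <= o.delta <= 12.0
            assert 0.05 <= o.J <= 3.0
            assert o.eps_H < case.energy < o.eps_L

    def test_distinct_seeds_differ(self):
        assert generate_fixtures(seed=1, n=5) != generate_fixtures(seed=2, n=5)

    def test_needs_at_least_one(self):
        with pytest.raises(ParameterValidationError):
            generate_fixtures(seed=1, n=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta_range": (5.0, 2.0, 10)},
            {"j_range": (0.5, 3.0, 1)},
            {"delta_range": (-1.0, 5.0, 10)},
            {"a": 0.0},
            {"L": -1.0},
            {"tau_floor": 1.5},
        ],
    )
    def test_rejects_bad_config(self, kwargs):
        with pytest.raises(ParameterValidationError):
            SweepConfig(**kwargs)
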