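"""DVH engine: curve construction and point metrics against enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbrtbench.dvh import (
    dose_mean,
    dose_quantile_pct,
    dose_to_hottest_volume,
    dvh,
    volume_at_dose_cm3,
    volume_at_dose_pct,
)
from sbrtbench.grids import StructureRole

from conftest import make_grid, make_mask


def sorted_voxel_quantile(doses, weights, pct):
    """Independent oracle for Dx%: walk voxels hottest-first until x% of the
    occupancy-weighted volume is accumulated; return that voxel's dose."""
    order = np.argsort(doses)[::-1]
    target = pct / 100.0 * weights.sum()
    acc = 0.0
    for idx in order:
        acc += weights[idx]
        if acc >= target - 1e-12:
            return doses[idx]
    return doses[order[-1]]


class TestCurve:
    def test_uniform_dose_step_curve(self):
        dose = np.full((10, 10, 10), 10.0)
        occ = np.ones((10, 10, 10))  # 1000 voxels of 1 mm^3 = 1 cm^3
        grid = make_grid(dose)
        curve = dvh(grid, make_mask(occ))
        assert curve.total_volume_cm3 == pytest.approx(1.0)
        below = curve.edges_gy <= 10.0
        np.testing.assert_allclose(curve.cum_volume_cm3[below], 1.0)
        assert np.all(np.diff(curve.cum_volume_cm3) <= 1e-12)

    def test_staircase_matches_threshold_counting(self):
        doses = np.arange(1.0, 11.0)  # 10 voxels, 1..10 Gy, 1 mm^3 each
        dose = np.zeros((10, 1, 1))
        dose[:, 0, 0] = doses
        occ = np.ones((10, 1, 1))
        curve = dvh(make_grid(dose), make_mask(occ))
        for i, edge in enumerate(curve.edges_gy):
            oracle = np.count_nonzero(doses >= edge) / 1000.0
            assert curve.cum_volume_cm3[i] == pytest.approx(oracle, abs=1e-12)

    def test_fractional_occupancy_weighting(self):
        dose = np.zeros((4, 1, 1))
        dose[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        occ = np.zeros((4, 1, 1))
        occ[:, 0, 0] = [0.5, 1.0, 0.5, 1.0]
        curve = dvh(make_grid(dose), make_mask(occ))
        for i, edge in enumerate(curve.edges_gy):
            oracle = occ[dose >= edge].sum() / 1000.0
            assert curve.cum_volume_cm3[i] == pytest.approx(oracle, abs=1e-15)

    def test_zero_volume_mask_raises(self):
        with pytest.raises(ValueError, match="zero volume"):
            dvh(make_grid(np.ones((3, 3, 3))), make_mask(np.zeros((3, 3, 3))))


class TestPointMetrics:
    def test_mean_of_staircase(self):
        dose = np.zeros((10, 1, 1))
        dose[:, 0, 0] = np.arange(1.0, 11.0)
        assert dose_mean(make_grid(dose), make_mask(np.ones((10, 1, 1)))) == pytest.approx(5.5)

    def test_uniform_64p5(self):
        dose = np.full((6, 6, 6), 64.5)
        occ = np.ones((6, 6, 6))
        grid, mask = make_grid(dose), make_mask(occ, StructureRole.ITV)
        curve = dvh(grid, mask)
        assert dose_quantile_pct(curve, 95) == pytest.approx(64.5, abs=0.1)
        assert volume_at_dose_pct(grid, mask, 58.1) == pytest.approx(100.0)

    @pytest.mark.parametrize("pct", [2, 50, 90, 95, 98])
    def test_quantiles_match_sorted_voxel_oracle(self, rng, pct):
        dose = rng.gamma(6.0, 8.0, size=(15, 14, 13))
        occ = rng.random((15, 14, 13))
        grid, mask = make_grid(dose), make_mask(occ)
        curve = dvh(grid, mask)
        got = dose_quantile_pct(curve, pct)
        oracle = sorted_voxel_quantile(dose.ravel(), occ.ravel(), pct)
        assert got == pytest.approx(oracle, abs=curve.bin_width_gy)

    def test_hottest_volume_matches_oracle(self, rng):
        dose = rng.random((12, 12, 12)) * 70
        occ = (rng.random((12, 12, 12)) > 0.3) * rng.random((12, 12, 12))
        occ[0, 0, :] = 1.0  # ensure nonzero volume
        grid, mask = make_grid(dose), make_mask(occ)
        curve = dvh(grid, mask)
        v = 0.1  # cm^3 = 100 voxels at 1 mm^3
        got = dose_to_hottest_volume(curve, v)
        w = occ.ravel()
        d = dose.ravel()
        order = np.argsort(d)[::-1]
        acc = np.cumsum(w[order]) / 1000.0
        oracle = d[order[np.searchsorted(acc, v - 1e-12)]]
        assert got == pytest.approx(oracle, abs=curve.bin_width_gy)

    def test_requested_volume_above_total_raises(self):
        curve = dvh(make_grid(np.ones((3, 3, 3))), make_mask(np.ones((3, 3, 3))))
        with pytest.raises(ValueError, match="exceeds"):
            dose_to_hottest_volume(curve, 1.0)

    @pytest.mark.parametrize("pct", [0, -5, 101])
    def test_quantile_percentage_domain(self, pct):
        curve = dvh(make_grid(np.ones((3, 3, 3))), make_mask(np.ones((3, 3, 3))))
        with pytest.raises(ValueError):
            dose_quantile_pct(curve, pct)


class TestProperties:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_quantile_monotone_and_vdose_monotone(self, seed):
        r = np.random.default_rng(seed)
        dose = r.random((8, 8, 8)) * 70
        occ = r.random((8, 8, 8))
        grid, mask = make_grid(dose), make_mask(occ)
        curve = dvh(grid, mask)
        qs = [dose_quantile_pct(curve, x) for x in (2, 25, 50, 75, 98)]
        assert all(a >= b - 1e-9 for a, b in zip(qs, qs[1:]))  # non-increasing in x
        d98, dmed, d2 = qs[4], qs[2], qs[0]
        assert d98 <= dmed + 1e-9 <= d2 + 2e-9
        assert volume_at_dose_pct(grid, mask, 0.0) == pytest.approx(100.0)
        vs = [volume_at_dose_cm3(grid, mask, d) for d in np.linspace(0, 70, 15)]
        assert all(a >= b - 1e-12 for a, b in zip(vs, vs[1:]))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_curve_mean_close_to_voxel_mean(self, seed):
        # trapezoidal mean from the binned curve vs the voxel-exact mean
        r = np.random.default_rng(seed)
        dose = r.random((10, 10, 10)) * 60
        occ = np.clip(r.random((10, 10, 10)) + 0.05, 0, 1)
        grid, mask = make_grid(dose), make_mask(occ)
        curve = dvh(grid, mask)
        # integral of the cumulative curve (normalized) over dose = mean dose
        curve_mean = np.trapezoid(
            curve.cum_volume_cm3 / curve.total_volume_cm3, curve.edges_gy
        )
        assert abs(curve_mean - dose_mean(grid, mask)) <= curve.bin_width_gy / 2
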