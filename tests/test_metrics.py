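"""Percentile curves, AUC quadrature, and the severity flag."""

import numpy as np
import pytest

from edrs import (
    ModelParams,
    auc_edrs,
    build_surface,
    normalize_trajectory,
    percentile_trajectories,
    severity_flag,
    summarize_surface,
)
from edrs.errors import ConsistencyError, InsufficientDataError, ParameterError
from edrs.metrics import TauSeries


def _constant_surface(levels, n_grid=100, invalid_prefix=0):
    """Surface of constant-elastance breaths, one per value in `levels`."""
    params = ModelParams(n_grid=n_grid)
    trajs = []
    for k, value in enumerate(levels):
        m = 60
        valid = np.ones(m, bool)
        edrs = np.full(m, float(value))
        if invalid_prefix:
            valid[:invalid_prefix] = False
            edrs[:invalid_prefix] = np.nan
        trajs.append(
            normalize_trajectory(edrs, valid, 0.8, params, breath_index=k)
        )
    return build_surface(trajs, "p", "PS")


def _series(func, n_grid=100):
    tau = np.linspace(0.0, 1.0, n_grid)
    return TauSeries(tau, func(tau), np.ones(n_grid, bool))


class TestPercentiles:
    def test_identical_breaths_give_constant_curves(self):
        surface = _constant_surface([30.0] * 10)
        summary = percentile_trajectories(surface)
        assert summary.valid.all()
        np.testing.assert_allclose(summary.values, 30.0)

    def test_odd_count_median(self):
        surface = _constant_surface([10.0, 20.0, 30.0])
        summary = percentile_trajectories(surface)
        np.testing.assert_allclose(summary.trajectory(50).edrs, 20.0)

    def test_matches_brute_force_order_statistics(self):
        # independent oracle: explicit linear interpolation between sorted
        # order statistics at each grid point
        rng = np.random.default_rng(8)
        n_breaths, n_grid = 200, 40
        params = ModelParams(n_grid=n_grid)
        trajs = []
        for k in range(n_breaths):
            m = 50
            edrs = 30.0 + 10.0 * rng.standard_normal() * np.linspace(0.5, 1.5, m)
            trajs.append(
                normalize_trajectory(edrs, np.ones(m, bool), 0.8, params,
                                     breath_index=k)
            )
        surface = build_surface(trajs, "p", "PS")
        summary = percentile_trajectories(surface, levels=(5, 25, 50, 75, 95))
        mat = surface.matrix()
        for j in range(n_grid):
            col = np.sort(mat[:, j])
            for i, level in enumerate(summary.levels):
                h = (col.size - 1) * level / 100.0
                lo = int(np.floor(h))
                hi = min(lo + 1, col.size - 1)
                expected = col[lo] + (h - lo) * (col[hi] - col[lo])
                assert summary.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_pointwise_ordering_everywhere(self):
        rng = np.random.default_rng(3)
        params = ModelParams(n_grid=60)
        trajs = []
        for k in range(50):
            m = 45
            edrs = rng.normal(25.0, 8.0) + rng.standard_normal(m)
            valid = np.ones(m, bool)
            valid[: rng.integers(0, 6)] = False
            edrs = np.where(valid, edrs, np.nan)
            trajs.append(normalize_trajectory(edrs, valid, 0.7, params, k))
        summary = percentile_trajectories(build_surface(trajs, "p", "PS"))
        vals = summary.values[:, summary.valid]
        assert np.all(np.diff(vals, axis=0) >= -1e-12)

    def test_grid_points_with_fewer_than_two_breaths_invalid(self):
        surface = _constant_surface([10.0, 20.0, 30.0], invalid_prefix=10)
        # knock all but one breath out at early tau by extending one prefix
        surface.trajectories[0].valid[:30] = False
        summary = percentile_trajectories(surface)
        assert not summary.valid[0]

    def test_empty_surface_rejected(self):
        from edrs.elastance import EdrsSurface

        with pytest.raises(ConsistencyError):
            percentile_trajectories(EdrsSurface("p", "PS", []))


class TestAUC:
    def test_constant_rectangle(self):
        assert auc_edrs(_series(lambda t: np.full_like(t, 40.0))) == pytest.approx(
            0.7 * 40.0, abs=1e-9
        )

    def test_linear_ramp_closed_form(self):
        # integral of 100*tau over [0.3, 1.0] = 100*(1 - 0.09)/2 = 45.5
        assert auc_edrs(_series(lambda t: 100.0 * t)) == pytest.approx(
            45.5, abs=1e-9
        )

    def test_agrees_with_fine_grid_quadrature_of_same_interpolant(self):
        rng = np.random.default_rng(5)
        coef = rng.standard_normal(4)
        func = lambda t: 30.0 + 8.0 * np.sin(2 * np.pi * t) * coef[0] \
            + 5.0 * np.cos(3 * np.pi * t) * coef[1] + coef[2] * t + coef[3]
        series = _series(func)
        fine = np.linspace(0.3, 1.0, 10_000)
        ref = np.trapezoid(np.interp(fine, series.tau, series.edrs), fine)
        assert auc_edrs(series) == pytest.approx(ref, rel=1e-3)

    def test_linearity_in_the_trajectory(self):
        series = _series(lambda t: 20.0 + 30.0 * t**2)
        a, b = 2.5, -4.0
        scaled = TauSeries(series.tau, a * series.edrs + b, series.valid)
        assert auc_edrs(scaled) == pytest.approx(
            a * auc_edrs(series) + 0.7 * b, abs=1e-9
        )

    def test_invalid_point_inside_window_rejected(self):
        series = _series(lambda t: np.full_like(t, 10.0))
        valid = series.valid.copy()
        valid[60] = False
        with pytest.raises(InsufficientDataError, match="tau"):
            auc_edrs(TauSeries(series.tau, series.edrs, valid))

    def test_bad_window_rejected(self):
        series = _series(lambda t: t)
        with pytest.raises(ParameterError):
            auc_edrs(series, window=(0.9, 0.3))


class TestSeverity:
    @pytest.mark.parametrize(
        "auc,expected", [(25.0, True), (24.999, False), (60.0, True), (-5.0, False)]
    )
    def test_threshold_boundary(self, auc, expected):
        assert severity_flag(auc) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            severity_flag(float("nan"))


class TestSummarise:
    def test_percentile_then_auc_of_identical_breaths(self):
        surface = _constant_surface([30.0] * 12)
        result = summarize_surface(surface)
        single = auc_edrs(surface.trajectories[0])
        for level in result.levels:
            assert result.auc_per_level[level] == pytest.approx(single, abs=1e-9)
        assert result.auc_per_level[50] == pytest.approx(21.0, abs=1e-9)

    def test_auc_ordering_follows_percentile_ordering(self):
        rng = np.random.default_rng(11)
        surface = _constant_surface(rng.normal(30, 10, 40))
        result = summarize_surface(surface)
        aucs = [result.auc_per_level[lv] for lv in result.levels]
        assert aucs == sorted(aucs)

    def test_flags_follow_threshold(self):
        surface = _constant_surface([20.0, 40.0, 60.0])
        result = summarize_surface(surface)
        assert result.severity_flag_per_level[5] is False  # 0.7*~21 < 25
        assert result.severity_flag_per_level[95] is True
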