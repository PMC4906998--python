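"""EFS time-course analysis: normalisation, trend fitting, synergism metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import synbath as sb
from synbath.errors import InvalidInputError
from synbath.timecourse import DeltaCurve


GRID = np.arange(0.0, 725.0, 5.0)


def onset(t, tau=18.3):
    return 1.0 - 2.0 ** (-np.asarray(t, float) / tau)


class TestNormalizeEfs:
    @pytest.mark.parametrize(
        "amp, want", [(2.0, 0.0), (0.0, 100.0), (1.6, 20.0)]
    )
    def test_anchors(self, amp, want):
        assert np.isclose(sb.normalize_efs(amp, 2.0), want)

    @given(
        scale=st.floats(0.1, 10.0),
        amp=st.floats(0.0, 3.0),
        ref=st.floats(0.5, 3.0),
    )
    def test_affine_invariance(self, scale, amp, ref):
        a = sb.normalize_efs(amp, ref)
        b = sb.normalize_efs(amp * scale, ref * scale)
        assert abs(a - b) < 1e-9 * max(1.0, abs(a))

    def test_nonpositive_reference(self):
        with pytest.raises(InvalidInputError):
            sb.normalize_efs([1.0], 0.0)


class TestFitTrend:
    def test_linear_data_recover_degree_one(self):
        t = GRID[:20]
        y = 3.0 + 0.5 * t
        trend = sb.fit_trend(t, y)
        assert trend.degree == 1
        assert np.allclose(trend.predict(t), y, atol=1e-9)

    def test_quadratic_data_recover_degree_two(self):
        t = GRID[:30]
        y = 1.0 - 0.01 * t + 2e-4 * t**2
        trend = sb.fit_trend(t, y)
        assert trend.degree == 2
        assert trend.rss <= 1e-9

    def test_underdetermined_trace(self):
        with pytest.raises(InvalidInputError):
            sb.fit_trend(GRID[:5], np.zeros(5), max_degree=4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_onset_recovered_from_saturating_trace(self, seed):
        # mean of 3 noisy subject traces; t1/2 truth is the onset half-time
        rng = np.random.default_rng(seed)
        y = 0.66 * onset(GRID) + rng.normal(0, 0.05 / np.sqrt(3), GRID.size)
        trend = sb.fit_trend(GRID, y)
        m = sb.compute_metrics(trend, GRID)
        assert m.t_half is not None
        assert abs(m.t_half - 18.3) <= 5.0  # one grid step


class TestComputeMetrics:
    def test_t_half_closed_form(self):
        m = sb.compute_metrics(lambda t: 40 * (1 - 2 ** (-np.asarray(t) / 18.3)), GRID)
        assert abs(m.t_half - 18.3) < 1e-3
        # monotone increasing trend peaks at the end of the experiment
        assert np.isclose(m.e_max, 40 * (1 - 2 ** (-720 / 18.3)), rtol=1e-9)

    def test_plateau_level(self):
        m = sb.compute_metrics(lambda t: 36.0 * onset(t, tau=30.0), GRID)
        assert abs(m.e_max_plateau - 36.0) < 0.5

    def test_trend_starting_above_half_max_flags_t_half(self):
        # strictly decreasing trend never crosses half-max from below
        m = sb.compute_metrics(lambda t: 40.0 - 0.01 * np.asarray(t), GRID)
        assert m.t_half is None


def make_delta_curve(delta_pct, p, times=None):
    times = GRID if times is None else times
    d = np.full(times.size, delta_pct / 100.0) if np.isscalar(delta_pct) \
        else np.asarray(delta_pct) / 100.0
    pv = np.full(times.size, p) if np.isscalar(p) else np.asarray(p)
    return DeltaCurve(times=times, delta=d, sem=np.zeros(times.size), p_values=pv)


class TestAucIntervals:
    def test_constant_delta(self):
        curve = make_delta_curve(20.0, 1.0)
        assert np.isclose(sb.auc_intervals(curve, [(0, 1)])["0-1"], 20.0, atol=1e-9)

    def test_triangular_delta(self):
        t = np.array([0.0, 360.0, 720.0])
        tri = DeltaCurve(
            times=t,
            delta=np.array([0.0, 0.30, 0.0]),
            sem=np.zeros(3),
            p_values=np.ones(3),
        )
        assert np.isclose(sb.auc_intervals(tri, [(0, 12)])["0-12"], 180.0, atol=1e-9)

    def test_additivity_over_adjacent_intervals(self):
        rng = np.random.default_rng(3)
        curve = make_delta_curve(rng.normal(20, 5, GRID.size), 1.0)
        auc = sb.auc_intervals(curve, [(0, 3), (3, 6), (0, 6)])
        assert abs(auc["0-6"] - (auc["0-3"] + auc["3-6"])) <= 1e-9

    def test_interval_beyond_range(self):
        curve = make_delta_curve(10.0, 1.0, times=GRID[GRID <= 360])
        with pytest.raises(InvalidInputError):
            sb.auc_intervals(curve, [(0, 12)])


class TestDuration:
    def test_all_points_significant(self):
        curve = make_delta_curve(20.0, 0.001)
        assert sb.duration_of_synergism(curve) == 12.0

    def test_no_point_significant(self):
        curve = make_delta_curve(20.0, 0.5)
        assert sb.duration_of_synergism(curve) == 0.0

    def test_negative_delta_not_counted(self):
        curve = make_delta_curve(-20.0, 0.001)
        assert sb.duration_of_synergism(curve) == 0.0

    def test_single_gap_is_bridged(self):
        p = np.full(GRID.size, 0.001)
        p[60] = 0.9  # one isolated dropout inside the run
        curve = make_delta_curve(20.0, p)
        assert sb.duration_of_synergism(curve) == 12.0

    def test_double_gap_breaks_the_run(self):
        p = np.full(GRID.size, 0.001)
        p[60:62] = 0.9
        sig_until = GRID[59] / 60.0
        curve = make_delta_curve(20.0, p)
        # the longest run is the tail segment; its end time still bounds it
        assert sb.duration_of_synergism(curve, gap_tolerance=0) == 12.0
        p2 = np.full(GRID.size, 0.9)
        p2[:60] = 0.001
        curve2 = make_delta_curve(20.0, p2)
        assert sb.duration_of_synergism(curve2) == pytest.approx(sig_until)


class TestSynergismCurve:
    def test_observed_equal_expectation_gives_zero_delta(self):
        single = np.tile(0.2 * onset(GRID), (3, 1))
        observed = 1.0 - (1.0 - single) ** 2
        out = sb.synergism_curve(observed, {"a": single, "b": single}, GRID,
                                 overall_test=False)
        assert np.allclose(out.delta, 0.0, atol=1e-12)

    def test_disjoint_grids_rejected(self):
        single = np.tile(0.2, (3, 10))
        with pytest.raises(InvalidInputError):
            sb.synergism_curve(
                np.tile(0.3, (3, 10)),
                {"a": single, "b": single},
                np.arange(10.0),
                expected_times=np.arange(100.0, 110.0),
            )

    def test_interpolation_is_recorded(self):
        t_obs = GRID[(GRID >= 10) & (GRID <= 700)]
        t_exp = GRID
        single = np.tile(0.2 * onset(t_exp), (3, 1))
        observed = np.tile(0.4 * onset(t_obs), (3, 1))
        out = sb.synergism_curve(
            observed, {"a": single, "b": single}, t_obs,
            expected_times=t_exp, overall_test=False,
        )
        assert out.interpolated

    def test_whole_curve_test_detects_sustained_synergy(self):
        rng = np.random.default_rng(4)
        single = 0.2 * onset(GRID) + rng.normal(0, 0.03, (3, GRID.size))
        observed = (
            1.0 - (1.0 - 0.2 * onset(GRID)) ** 2
            + 0.30 * onset(GRID)
            + rng.normal(0, 0.03, (3, GRID.size))
        ).clip(0, 1)
        out = sb.synergism_curve(observed, {"a": single, "b": single}, GRID)
        assert out.overall_p < 1e-6


class TestCompareCombinations:
    def test_mismatched_intervals_rejected(self):
        a = sb.CombinationMetrics(
            "a", {"0-1": (20.0, 8.0)}, (18.3, 9.3), (25.9, 9.4), (9.0, 0.2)
        )
        b = sb.CombinationMetrics(
            "b", {"0-3": (100.0, 10.0)}, (15.5, 3.5), (42.9, 7.6), (6.0, 0.2)
        )
        with pytest.raises(InvalidInputError):
            sb.compare_combinations(a, b)

    def test_difference_direction(self):
        a = sb.CombinationMetrics(
            "a", {"0-1": (20.0, 8.0)}, (18.3, 9.3), (25.9, 9.4), (9.0, 0.2)
        )
        b = sb.CombinationMetrics(
            "b", {"0-1": (27.0, 3.5)}, (15.5, 3.5), (42.9, 7.6), (6.0, 0.2)
        )
        table = sb.compare_combinations(a, b).set_index("metric")
        assert table.loc["duration_h", "difference"] == pytest.approx(3.0)
        assert table.loc["auc_0-1_h", "difference"] == pytest.approx(-7.0)
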