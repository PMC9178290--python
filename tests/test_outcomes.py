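"""Outcome extraction and comparison metrics, with brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensekit.fe_io import KinematicsSeries
from sensekit.outcomes import (
    AnalysisError,
    aggregate_parameter,
    analyze_group,
    compare_run,
    convergence_pct_diff,
    location_distance,
    peak_contact_pressure,
    pressure_pct_diff,
    select_analysis_time,
    valgus_rmse,
)
from sensekit.synth import EffectConfig, simulate_run
from conftest import make_frame


def brute_force_peak(pressures, centroids, face_ids):
    """Independent oracle: sort by hand, average the top ceil(10%)."""
    rows = [
        (p, fid, c)
        for p, fid, c in zip(pressures, face_ids, centroids)
        if p > 0
    ]
    if not rows:
        return None, None, 0, 0
    n_top = math.ceil(0.1 * len(rows))
    rows.sort(key=lambda r: (-r[0], r[1]))
    top = rows[:n_top]
    peak = sum(r[0] for r in top) / n_top
    loc = np.mean([r[2] for r in top], axis=0)
    return peak, loc, len(rows), n_top


class TestPeakContactPressure:
    def test_ten_faces_top_set_is_single_maximum(self):
        s = peak_contact_pressure(make_frame(np.arange(1.0, 11.0)))
        assert s.n_contact_faces == 10
        assert s.n_top_faces == 1
        assert s.peak_pressure == pytest.approx(10.0)

    def test_fifteen_faces_round_up_to_two(self):
        s = peak_contact_pressure(make_frame(np.arange(1.0, 16.0)))
        assert s.n_top_faces == 2
        assert s.peak_pressure == pytest.approx((15 + 14) / 2)

    def test_uniform_pressure_field_peak_equals_value(self):
        s = peak_contact_pressure(make_frame(np.full(37, 2.5)))
        assert s.peak_pressure == pytest.approx(2.5)

    def test_zero_contact_yields_no_contact_summary(self):
        s = peak_contact_pressure(make_frame(np.zeros(8)))
        assert not s.has_contact
        assert s.peak_pressure is None and s.location is None

    @given(
        st.lists(st.floats(min_value=0.0, max_value=50.0), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle_under_permutation(self, pressures, rnd):
        n = len(pressures)
        centroids = np.column_stack([np.arange(n), np.arange(n) % 3, np.zeros(n)]).astype(float)
        order = list(range(n))
        rnd.shuffle(order)
        frame = make_frame(
            np.asarray(pressures)[order],
            centroids=centroids[order],
            face_ids=np.arange(n)[order],
        )
        summary = peak_contact_pressure(frame)
        peak, loc, n_contact, n_top = brute_force_peak(pressures, centroids, np.arange(n))
        assert summary.n_contact_faces == n_contact
        assert summary.n_top_faces == n_top
        if peak is None:
            assert summary.peak_pressure is None
        else:
            assert summary.peak_pressure == pytest.approx(peak)
            np.testing.assert_allclose(summary.location, loc, atol=1e-12)


class TestAnalysisTimeSelection:
    def _result(self, t_last, small_model):
        eff = EffectConfig()
        from sensekit.synth import Effect

        eff = EffectConfig(per_axis={"penalty_factor": Effect(truncate_time=t_last)})
        from sensekit.design import Category, PerturbationPlan

        plan = PerturbationPlan("synth01", "penalty_factor", Category.CONTACT, 2.0)
        return simulate_run(plan, small_model, eff, "valgus")

    def test_latest_common_time_selected(self, small_model):
        base = simulate_run(None, small_model, EffectConfig(), "valgus")
        runs = [self._result(3.0, small_model), self._result(2.6, small_model)]
        t, included, excluded = select_analysis_time(base, runs)
        assert t == pytest.approx(2.6)
        assert len(included) == 2 and not excluded

    def test_run_stopping_before_threshold_is_excluded(self, small_model):
        base = simulate_run(None, small_model, EffectConfig(), "valgus")
        runs = [self._result(3.0, small_model), self._result(2.1, small_model)]
        t, included, excluded = select_analysis_time(base, runs)
        assert t == pytest.approx(3.0)
        assert len(excluded) == 1
        assert "2.25" in excluded[0][1]

    def test_all_members_fully_converged(self, small_model):
        base = simulate_run(None, small_model, EffectConfig(), "valgus")
        runs = [self._result(3.0, small_model)]
        t, _, _ = select_analysis_time(base, runs)
        assert t == pytest.approx(3.0)

    def test_unconverged_baseline_is_group_error(self, small_model):
        bad_base = self._result(2.2, small_model)
        with pytest.raises(AnalysisError, match="baseline"):
            select_analysis_time(bad_base, [])


class TestConvergenceMetric:
    @pytest.mark.parametrize(
        "t_int, t_orig, expected",
        [(3.0, 3.0, 0.0), (2.25, 3.0, 25.0), (1.5, 3.0, 50.0)],
    )
    def test_percentage_difference(self, t_int, t_orig, expected):
        assert convergence_pct_diff(t_int, t_orig) == pytest.approx(expected)

    def test_zero_original_time_rejected(self):
        with pytest.raises(AnalysisError):
            convergence_pct_diff(1.0, 0.0)


def _series(times, valgus):
    times = np.asarray(times, float)
    values = np.zeros((times.size, 6))
    values[:, 1] = valgus
    return KinematicsSeries(times, values)


class TestValgusRmse:
    def test_identical_series_zero(self):
        s = _series([2.0, 2.5, 3.0], [0.0, 1.0, 2.0])
        assert valgus_rmse(s, s) == pytest.approx(0.0)

    def test_constant_offset_recovered_exactly(self):
        t = [2.0, 2.25, 2.5, 2.75, 3.0]
        a = _series(t, np.linspace(0, 4, 5))
        b = _series(t, np.linspace(0, 4, 5) + 0.7)
        assert valgus_rmse(a, b) == pytest.approx(0.7)

    def test_interpolation_onto_finer_interest_grid(self):
        # original linear theta(t) = t on {2.0, 3.0}; interest theta(t) = t + 0.5
        original = _series([2.0, 3.0], [2.0, 3.0])
        interest = _series([2.0, 2.5, 3.0], [2.5, 3.0, 3.5])
        assert valgus_rmse(original, interest) == pytest.approx(0.5)

    def test_shared_constant_added_to_both_series_is_invisible(self):
        t = [2.0, 2.5, 3.0]
        a = _series(t, [0.0, 1.0, 2.0])
        b = _series(t, [0.5, 1.2, 2.4])
        base = valgus_rmse(a, b)
        a2 = _series(t, np.array([0.0, 1.0, 2.0]) + 5.0)
        b2 = _series(t, np.array([0.5, 1.2, 2.4]) + 5.0)
        assert valgus_rmse(a2, b2) == pytest.approx(base)

    def test_no_overlap_returns_none(self):
        a = _series([2.0, 2.05], [0.0, 0.1])
        b = _series([2.5, 3.0], [0.0, 0.1])
        # interest times all beyond the original's last converged step
        assert valgus_rmse(a, b) is None


def _summaries(med_p, lat_p, med_loc=(0, 0, 0), lat_loc=(0, 0, 0)):
    from sensekit.outcomes import PeakPressureSummary

    return {
        "medial": PeakPressureSummary("medial", med_p, np.asarray(med_loc, float), 10, 1),
        "lateral": PeakPressureSummary("lateral", lat_p, np.asarray(lat_loc, float), 10, 1),
    }


class TestPressureAndLocationMetrics:
    def test_side_percentages_averaged(self):
        orig = _summaries(2.0, 2.0)
        interest = _summaries(2.8, 2.2)  # +40% medial, +10% lateral
        value, signed = pressure_pct_diff(interest, orig)
        assert value == pytest.approx(25.0)
        assert signed["medial"] == pytest.approx(40.0)

    def test_identity_and_scaling(self):
        orig = _summaries(2.0, 3.0)
        same, _ = pressure_pct_diff(orig, orig)
        assert same == pytest.approx(0.0)
        scaled = _summaries(3.0, 4.5)
        value, _ = pressure_pct_diff(scaled, orig)
        assert value == pytest.approx(50.0)

    def test_location_pythagoras_and_side_mean(self):
        orig = _summaries(2.0, 2.0)
        interest = _summaries(2.0, 2.0, med_loc=(3, 4, 0))
        assert location_distance(interest, orig) == pytest.approx(2.5)

    def test_location_invariant_under_common_rigid_translation(self):
        orig = _summaries(2.0, 2.0, med_loc=(1, 2, 3), lat_loc=(4, 5, 6))
        interest = _summaries(2.0, 2.0, med_loc=(2, 2, 3), lat_loc=(4, 5, 6))
        d0 = location_distance(interest, orig)
        shift = np.array([10.0, -7.0, 2.0])
        orig_s = _summaries(2.0, 2.0, med_loc=np.array([1, 2, 3]) + shift, lat_loc=np.array([4, 5, 6]) + shift)
        int_s = _summaries(2.0, 2.0, med_loc=np.array([2, 2, 3]) + shift, lat_loc=np.array([4, 5, 6]) + shift)
        assert location_distance(int_s, orig_s) == pytest.approx(d0)

    def test_side_without_baseline_contact_is_dropped(self):
        from sensekit.outcomes import PeakPressureSummary

        orig = {
            "medial": PeakPressureSummary("medial", 2.0, np.zeros(3), 10, 1),
            "lateral": PeakPressureSummary("lateral", None, None, 0, 0),
        }
        interest = _summaries(3.0, 1.0)
        value, signed = pressure_pct_diff(interest, orig)
        assert value == pytest.approx(50.0)
        assert "lateral" not in signed


class TestAggregation:
    def _comparison(self, direction="valgus", pressure=10.0, excluded=False):
        from sensekit.outcomes import OutcomeComparison

        return OutcomeComparison(
            plan_id="p", direction=direction, analysis_time=3.0,
            convergence_pct_diff=5.0, convergence_diff_signed=-5.0,
            valgus_rmse=None if excluded else 0.3,
            pressure_pct_diff=None if excluded else pressure,
            pressure_diff_signed={}, location_distance=None if excluded else 1.0,
            excluded=excluded, exclusion_reason="stopped" if excluded else "",
        )

    def test_single_comparison_aggregate_equals_it(self):
        agg = aggregate_parameter([self._comparison(pressure=10.0)], "valgus")
        assert agg.pressure_pct_diff == pytest.approx(10.0)
        assert agg.n_runs == 1 and agg.n_excluded == 0

    def test_mean_of_two(self):
        comps = [self._comparison(pressure=10.0), self._comparison(pressure=30.0)]
        assert aggregate_parameter(comps, "valgus").pressure_pct_diff == pytest.approx(20.0)

    def test_excluded_runs_count_toward_convergence_only(self):
        comps = [
            self._comparison(pressure=10.0),
            self._comparison(pressure=30.0),
            self._comparison(excluded=True),
        ]
        agg = aggregate_parameter(comps, "valgus")
        assert agg.n_excluded == 1
        assert agg.pressure_pct_diff == pytest.approx(20.0)  # over the retained two
        assert agg.convergence_pct_diff == pytest.approx(5.0)  # over all three

    def test_directions_kept_separate(self):
        comps = [self._comparison("valgus", 10.0), self._comparison("varus", 30.0)]
        assert aggregate_parameter(comps, "valgus").pressure_pct_diff == pytest.approx(10.0)
        assert aggregate_parameter(comps, "varus").pressure_pct_diff == pytest.approx(30.0)

    def test_all_excluded_leaves_pressure_unavailable(self):
        agg = aggregate_parameter([self._comparison(excluded=True)], "valgus")
        assert agg.pressure_pct_diff is None
        assert agg.convergence_pct_diff is not None
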