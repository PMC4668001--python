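"""State classification, threshold calibration, occupancy statistics."""

import numpy as np
import pytest

from bcct import states as st
from bcct.states import (Thresholds, calibrate_open_threshold,
                         classify_frames, distance_water_correlation,
                         effective_sample_size, segment_states,
                         state_probabilities)


class TestThresholds:
    def test_defaults(self):
        t = Thresholds.default()
        assert (t.theta_open, t.theta_wide) == (8.7, 10.7)
        t = Thresholds.default("P28-G8")
        assert (t.theta_open, t.theta_wide) == (9.5, 15.0)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            Thresholds("x", 10.7, 8.7)
        with pytest.raises(ValueError):
            Thresholds("x", -1.0, 8.7)

    def test_unknown_pair_default(self):
        with pytest.raises(KeyError):
            Thresholds.default("F24-L15")


class TestClassification:
    def test_half_open_boundaries(self):
        t = Thresholds("Y26-V12", 8.7, 10.7)
        d = np.array([8.69, 8.7, 10.69, 10.7, 5.0, 20.0])
        labels = classify_frames(d, t).labels
        assert list(labels) == ["closed", "open", "open", "wide_open",
                                "closed", "wide_open"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_frames(np.array([]), Thresholds("x", 8.7, 10.7))

    def test_probabilities_sum_to_one(self, wt_traj):
        labels = classify_frames(wt_traj.series["Y26-V12"],
                                 Thresholds.default())
        table = state_probabilities(labels)
        assert sum(table.probabilities.values()) == pytest.approx(1.0,
                                                                  abs=0.0)
        for s, p in table.probabilities.items():
            assert 0.0 <= p <= 1.0
            assert table.standard_errors[s] >= 0.0

    def test_ess_not_larger_than_n(self, wt_traj):
        labels = classify_frames(wt_traj.series["Y26-V12"],
                                 Thresholds.default())
        table = state_probabilities(labels, use_ess=True)
        assert 1.0 <= table.ess <= table.n_frames
        # correlated frames: ESS-based errors are wider than naive ones
        naive = state_probabilities(labels)
        for s in table.probabilities:
            assert table.standard_errors[s] >= naive.standard_errors[s]


class TestCalibration:
    def test_gate_recovered_on_step_data(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(6.0, 12.0, 20000)
        water = (d > 8.7).astype(int) * rng.poisson(4, 20000)
        theta = calibrate_open_threshold(d, water, bin_width=0.1)
        assert abs(theta - 8.7) <= 0.1

    def test_all_dry_falls_back_with_warning(self):
        d = np.linspace(6, 12, 1000)
        with pytest.warns(UserWarning, match="falling back"):
            theta = calibrate_open_threshold(d, np.zeros(1000))
        assert theta == 8.7

    def test_all_wet_falls_back_with_warning(self):
        d = np.linspace(6, 12, 1000)
        with pytest.warns(UserWarning):
            theta = calibrate_open_threshold(d, np.ones(1000))
        assert theta == 8.7

    def test_no_fallback_for_unknown_pair(self):
        d = np.linspace(6, 12, 100)
        with pytest.raises(ValueError, match="fallback"):
            calibrate_open_threshold(d, np.zeros(100), pair_label="c0")

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            calibrate_open_threshold(np.ones(5), np.ones(4))


class TestSegments:
    def test_runs_without_merging(self):
        labels = np.array(["closed", "closed", "open", "wide_open"],
                          dtype=object)
        segs = segment_states(labels)
        assert segs == [("closed", 0, 2), ("open", 2, 3),
                        ("wide_open", 3, 4)]

    def test_flicker_merged_into_longer_neighbour(self):
        labels = np.array(["closed", "open", "closed", "closed"],
                          dtype=object)
        assert segment_states(labels, min_dwell=2) == [("closed", 0, 4)]

    def test_tie_goes_to_preceding(self):
        labels = np.array(["closed", "closed", "open", "wide_open",
                           "wide_open"], dtype=object)
        segs = segment_states(labels, min_dwell=2)
        assert segs == [("closed", 0, 3), ("wide_open", 3, 5)]

    def test_single_run_never_removed(self):
        labels = np.array(["open"], dtype=object)
        assert segment_states(labels, min_dwell=10) == [("open", 0, 1)]

    def test_empty(self):
        assert segment_states(np.array([], dtype=object)) == []

    def test_coverage_partition(self, wt_traj):
        labels = classify_frames(wt_traj.series["Y26-V12"],
                                 Thresholds.default())
        segs = segment_states(labels, min_dwell=3)
        assert segs[0][1] == 0 and segs[-1][2] == labels.n_frames
        for (s1, a1, b1), (s2, a2, b2) in zip(segs, segs[1:]):
            assert b1 == a2 and s1 != s2
            assert b2 - a2 >= 3 or len(segs) == 1
        assert all(b - a >= 3 for _, a, b in segs)


class TestEffectiveSampleSize:
    def test_iid_close_to_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20000)
        ess = effective_sample_size(x)
        assert 0.8 * 20000 <= ess <= 1.2 * 20000

    def test_correlated_much_smaller(self):
        rng = np.random.default_rng(0)
        x = np.zeros(20000)
        for t in range(1, 20000):
            x[t] = 0.95 * x[t - 1] + rng.normal()
        ess = effective_sample_size(x)
        # AR(1) with phi=0.95: tau = (1+phi)/(1-phi) = 39
        assert 200 <= ess <= 2000

    def test_constant_series(self):
        assert effective_sample_size(np.ones(100)) == 100


class TestCorrelation:
    def test_monotone_function_r_one(self):
        d = np.linspace(5, 15, 500)
        res = distance_water_correlation(d, 2.0 * d + 1.0)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_flagged(self):
        res = distance_water_correlation(np.full(10, 9.0), np.zeros(10))
        assert res.degenerate
        assert np.isnan(res.pearson_r)

    def test_contingency_counts(self):
        d = np.array([8.0, 8.0, 9.0, 9.0])
        w = np.array([0, 1, 0, 2])
        res = distance_water_correlation(d, w,
                                         Thresholds("Y26-V12", 8.7, 10.7))
        assert res.contingency.tolist() == [[1, 1], [1, 1]]
        assert res.contingency.sum() == 4
        assert res.p_wet_given_open == pytest.approx(0.5)

    def test_positive_on_synthetic(self, wt_traj):
        res = distance_water_correlation(wt_traj.series["Y26-V12"],
                                         wt_traj.water_counts)
        assert res.pearson_r > 0.4
        assert res.p_wet_given_open > res.p_wet_given_closed
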