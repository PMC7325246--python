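import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdegron.assay import (DegradationResult, TimeCourse, degradation_percent,
                            fit_decay_rate, fold_change, net_effect, normalize,
                            percent_of_control, quantify_degradation,
                            recovery_index)
from ctdegron.errors import DataError, FormatError, InvalidArgumentError
from ctdegron.simulate import TimeCourseSimConfig, simulate_timecourse


def make_tc(time, fluorescence, od, condition="tagged", genotype="WT", replicate=1):
    return TimeCourse(pd.DataFrame({
        "time_h": time,
        "fluorescence": fluorescence,
        "od600": od,
        "condition": condition,
        "genotype": genotype,
        "replicate": replicate,
    }))


class TestTimeCourseValidation:
    def test_missing_column_named(self):
        with pytest.raises(FormatError, match="od600"):
            TimeCourse(pd.DataFrame({
                "time_h": [0], "fluorescence": [1],
                "condition": ["tagged"], "genotype": ["WT"], "replicate": [1],
            }))

    def test_unknown_genotype_listed(self):
        with pytest.raises(DataError, match="dFtsH"):
            make_tc([0, 1], [1, 2], [1, 1], genotype="dFtsH")

    def test_non_increasing_time_rejected(self):
        with pytest.raises(DataError):
            make_tc([0, 2, 1], [1, 2, 3], [1, 1, 1])


class TestNormalize:
    def test_unit_od(self):
        ns = normalize(make_tc([0.0, 1.0], [100.0, 100.0], [1.0, 1.0]))
        np.testing.assert_allclose(ns.mean, [100.0, 100.0])

    def test_proportionality(self):
        ns = normalize(make_tc([0.0], [50.0], [0.5]))
        assert ns.mean[0] == pytest.approx(100.0)

    def test_constant_fluorescence_growing_od_decreases(self):
        t = np.arange(10.0)
        od = np.linspace(0.1, 2.0, 10)
        ns = normalize(make_tc(t, np.full(10, 100.0), od))
        assert (np.diff(ns.mean) < 0).all()

    def test_low_od_masked(self):
        ns = normalize(make_tc([0.0, 1.0, 2.0], [1.0, 2.0, 3.0],
                               [0.001, 1.0, 1.0]))
        assert ns.n_masked == 1
        assert len(ns.time) == 2

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        t = np.arange(5.0)
        f = np.array([10.0, 20.0, 30.0, 25.0, 15.0])
        od = np.array([0.2, 0.5, 1.0, 1.5, 1.8])
        a = normalize(make_tc(t, f, od))
        b = normalize(make_tc(t, f * c, od * c))
        np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)

    def test_replicates_averaged_after_normalization(self):
        df = pd.concat([
            make_tc([0.0, 1.0], [10.0, 10.0], [1.0, 1.0], replicate=1).df,
            make_tc([0.0, 1.0], [10.0, 10.0], [0.5, 0.5], replicate=2).df,
        ], ignore_index=True)
        ns = normalize(TimeCourse(df))
        np.testing.assert_allclose(ns.mean, [15.0, 15.0])
        assert ns.n_replicates == 2


class TestPercentOfControl:
    def test_self_control_is_100(self):
        tc = make_tc(np.arange(5.0), [10, 20, 30, 40, 50.0], np.ones(5))
        ns = normalize(tc)
        assert percent_of_control(ns, ns, 2.5) == pytest.approx(100.0)

    def test_endpoint_ratio_30h(self):
        t = [0.0, 30.0]
        tagged = normalize(make_tc(t, [8.6, 8.6], [1.0, 1.0]))
        control = normalize(make_tc(t, [100.0, 100.0], [1.0, 1.0],
                                    condition="untagged-control"))
        assert percent_of_control(tagged, control, 30.0) == pytest.approx(8.6)

    def test_complement_at_25h(self):
        t = [0.0, 25.0]
        tagged = normalize(make_tc(t, [38.0, 38.0], [1.0, 1.0]))
        control = normalize(make_tc(t, [100.0, 100.0], [1.0, 1.0],
                                    condition="untagged-control"))
        assert percent_of_control(tagged, control, 25.0) == pytest.approx(38.0)
        assert degradation_percent(tagged, control, 25.0) == pytest.approx(62.0)

    def test_out_of_range_errors(self):
        ns = normalize(make_tc([0.0, 10.0], [1.0, 1.0], [1.0, 1.0]))
        with pytest.raises(DataError):
            percent_of_control(ns, ns, 11.0)

    def test_identical_series_zero_degradation(self):
        ns = normalize(make_tc([0.0, 5.0], [7.0, 9.0], [1.0, 1.0]))
        assert degradation_percent(ns, ns, 3.0) == pytest.approx(0.0)

    @given(st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=30, deadline=None)
    def test_sum_identity_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(6.0)
        tagged = normalize(make_tc(t, rng.uniform(1, 100, 6), rng.uniform(0.5, 2, 6)))
        control = normalize(make_tc(t, rng.uniform(1, 100, 6), rng.uniform(0.5, 2, 6),
                                    condition="untagged-control"))
        at = rng.uniform(0, 5)
        assert (percent_of_control(tagged, control, at)
                + degradation_percent(tagged, control, at)) == pytest.approx(100.0)


class TestRecoveryIndex:
    def wt_ko(self, wt_deg, ko_deg, t=25.0):
        wt = DegradationResult("tagged", "WT", t, 100.0 - wt_deg)
        ko = DegradationResult("tagged", "dClpA", t, 100.0 - ko_deg)
        return wt, ko

    def test_forty_point_recovery(self):
        wt, ko = self.wt_ko(90.0, 50.0)
        assert recovery_index(ko, wt) == pytest.approx(40.0)

    def test_equal_is_zero(self):
        wt, ko = self.wt_ko(75.0, 75.0)
        assert recovery_index(ko, wt) == 0.0

    def test_endpoint_mismatch_rejected(self):
        wt = DegradationResult("tagged", "WT", 25.0, 10.0)
        ko = DegradationResult("tagged", "dClpA", 30.0, 50.0)
        with pytest.raises(InvalidArgumentError):
            recovery_index(ko, wt)

    def test_simulated_halved_decay_positive_index(self):
        cfg = TimeCourseSimConfig(noise_cv=0.01, seed=8, od_rate=0.0)
        control = simulate_timecourse(cfg, tagged=False)
        wt_tc = simulate_timecourse(cfg, tagged=True)
        ko_tc = simulate_timecourse(cfg, tagged=True, genotype="dClpA",
                                    decay_scale=0.5)
        wt = quantify_degradation(wt_tc, control, 25.0)
        ko_ctrl = simulate_timecourse(
            TimeCourseSimConfig(**{**cfg.__dict__}), tagged=False, genotype="dClpA")
        ko = quantify_degradation(ko_tc, ko_ctrl, 25.0)
        assert recovery_index(ko, wt) > 0


class TestFitDecayRate:
    def test_noiseless_rate_recovered_to_1e6(self):
        cfg = TimeCourseSimConfig(noise_cv=0.0, synthesis_rate=0.0,
                                  decay_rate=0.2, f0=1000.0, od_rate=0.0, seed=1)
        fit = fit_decay_rate(normalize(simulate_timecourse(cfg, tagged=True)))
        assert fit.rate == pytest.approx(0.2, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_series_flagged(self):
        ns = normalize(make_tc(np.arange(6.0), np.full(6, 50.0), np.ones(6)))
        fit = fit_decay_rate(ns)
        assert fit.rate == 0.0
        assert fit.flag == "not-degrading"

    def test_no_post_peak_segment(self):
        ns = normalize(make_tc([0.0, 1.0, 2.0], [1.0, 2.0, 3.0], np.ones(3)))
        fit = fit_decay_rate(ns)
        assert fit.flag == "not-estimable"

    def test_recovery_within_10pct_across_20_seeds(self):
        errors = []
        for seed in range(20):
            cfg = TimeCourseSimConfig(noise_cv=0.05, synthesis_rate=0.0,
                                      decay_rate=0.2, f0=1000.0,
                                      od_rate=0.0, n_replicates=3, seed=seed)
            fit = fit_decay_rate(normalize(simulate_timecourse(cfg, tagged=True)))
            errors.append(abs(fit.rate - 0.2) / 0.2)
        assert max(errors) <= 0.10


class TestFoldChange:
    def test_printed_convention_547(self):
        fc = fold_change(90.9, 16.6)
        assert fc.display == 5.47
        assert fc.direction == "decrease"

    def test_equality_is_none(self):
        fc = fold_change(10.0, 10.0)
        assert fc.display == 1.00
        assert fc.direction == "none"

    def test_increase_truncated(self):
        fc = fold_change(3.1, 3.9)
        assert fc.direction == "increase"
        assert fc.display == 1.25

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fold_change(0.0, 1.0)

    @given(st.floats(min_value=0.1, max_value=1000.0),
           st.floats(min_value=0.1, max_value=1000.0))
    @settings(max_examples=100, deadline=None)
    def test_argument_swap_keeps_fold(self, a, b):
        f1, f2 = fold_change(a, b), fold_change(b, a)
        assert f1.fold == f2.fold
        assert f1.fold >= 1.0
        if a != b:
            assert {f1.direction, f2.direction} == {"increase", "decrease"}


class TestNetEffect:
    def test_abundance_cannot_compensate(self):
        ne = net_effect(2.65, 5.47)
        assert ne.predicted_fold == pytest.approx(0.484, abs=5e-4)
        assert ne.direction == "decrease"

    def test_abundance_wins(self):
        ne = net_effect(3.3, 1.14)
        assert ne.predicted_fold == pytest.approx(2.89, abs=5e-3)
        assert ne.direction == "increase"

    def test_neutral(self):
        ne = net_effect(1.0, 1.0)
        assert ne.predicted_fold == 1.0
        assert ne.direction == "neutral"

    def test_ratio_below_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            net_effect(0.5, 2.0)
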