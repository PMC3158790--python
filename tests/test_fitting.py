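"""Episode fitting: binning, smoothing, switchover detection, staged fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntpsleep.cascade import EpisodeModel, ModeOccupancy, PhasePlan
from ntpsleep.fitting import (
    FitConfig,
    PowerTimeCourse,
    classify_fit,
    coefficient_of_determination,
    detect_switchovers,
    fit_episode,
    overall_r2,
    rebin_normalize,
    smooth3,
)
from ntpsleep.synthetic import NoiseModel, generate_episode_data


class TestRebinNormalize:
    def test_constant_series_fills_all_bins(self):
        t = np.linspace(0, 99.9, 500)
        tc = rebin_normalize(t, {"delta": np.full(500, 7.0)}, 0.0, 100.0)
        assert tc.n_bins == 50
        assert np.allclose(tc.bands["delta"], 7.0)

    def test_samples_in_first_half_leave_last_bins_missing(self):
        t = np.linspace(0, 49.9, 250)
        tc = rebin_normalize(t, {"delta": np.ones(250)}, 0.0, 100.0)
        assert np.all(np.isnan(tc.bands["delta"][25:]))
        assert not np.any(np.isnan(tc.bands["delta"][:25]))

    def test_linear_ramp_bin_means_at_bin_centers(self):
        # analytic mean of a linear 0..100 ramp over each 2% bin = bin center
        t = np.linspace(0, 100, 100001)
        tc = rebin_normalize(t, {"delta": t.copy()}, 0.0, 100.0)
        assert np.allclose(tc.bands["delta"], tc.time, atol=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rebin_normalize([], {"delta": []}, 0.0, 100.0)

    def test_all_missing_band_rejected(self):
        with pytest.raises(ValueError):
            rebin_normalize([1.0, 2.0], {"delta": [np.nan, np.nan]}, 0.0, 100.0)


class TestSmooth3:
    def test_constant_unchanged(self):
        assert np.allclose(smooth3([4.0] * 10), 4.0)

    def test_alternating_series(self):
        out = smooth3([0, 3, 0, 3, 0])
        assert out[1:4] == pytest.approx([1.0, 2.0, 1.0])
        assert out[0] == pytest.approx(1.5)

    def test_impulse_becomes_plateau(self):
        out = smooth3([0, 0, 0, 9, 0, 0, 0])
        assert out[2:5] == pytest.approx([3.0, 3.0, 3.0])

    def test_missing_values_excluded_from_local_mean(self):
        out = smooth3([1.0, np.nan, 3.0, 3.0, 3.0])
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(3.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth3([1.0, 2.0])


class TestDetectSwitchovers:
    def test_monotone_series_gives_single_phase(self):
        plan = detect_switchovers(np.linspace(0, 1, 50))
        assert plan.switchover_times == ()
        assert plan.n_towards == 1

    def test_single_rise_then_fall(self):
        x = np.concatenate([np.linspace(0, 1, 25), np.linspace(1, 0.2, 25)[1:]])
        x = np.append(x, 0.19)
        plan = detect_switchovers(x)
        assert len(plan.switchover_times) == 1
        assert plan.switchover_times[0] == pytest.approx(49.0, abs=2.0)

    def test_roundtrip_recovers_generating_plan(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model,
                                     NoiseModel(sigma=0.0), seed=0)
        plan = detect_switchovers(smooth3(data.bands["delta"]), data.time)
        true = np.array(three_cycle_model.plan.switchover_times)
        est = np.array(plan.switchover_times)
        assert est.size == true.size
        assert np.max(np.abs(est - true)) <= 2.0 + 1e-9  # within one 2% bin

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            detect_switchovers([1.0, 2.0, 3.0, 4.0])


class TestCoefficientOfDetermination:
    def test_perfect_prediction(self):
        assert coefficient_of_determination([1, 2, 3], [1, 2, 3]) == 100.0

    def test_mean_prediction_scores_zero(self):
        assert coefficient_of_determination([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert coefficient_of_determination([1, 2, 3], [1, 2, 4]) == pytest.approx(50.0)

    def test_can_be_negative(self):
        assert coefficient_of_determination([1, 2, 3], [3, 2, 1]) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_determination([2, 2, 2], [1, 2, 3])

    def test_missing_pairs_excluded(self):
        r = coefficient_of_determination([1, np.nan, 3, 4], [1, 9, 3, 4])
        assert r == 100.0


class TestOverallR2:
    def test_reproduces_printed_caption_values(self):
        assert round(overall_r2(97.8, 82.0, 90.3), 1) == 92.6
        assert round(overall_r2(88.6, 63.6, 84.7), 1) == 81.2

    @given(st.floats(1.0, 99.0))
    @settings(max_examples=30, deadline=None)
    def test_fixed_point_on_equal_inputs(self, x):
        assert overall_r2(x, x, x) == pytest.approx(x, rel=1e-9)

    @given(st.floats(5.0, 95.0), st.floats(5.0, 95.0), st.floats(5.0, 95.0))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, a, b, c):
        v = overall_r2(a, b, c)
        assert v == pytest.approx(overall_r2(c, a, b), rel=1e-12)
        assert min(a, b, c) - 1e-9 <= v <= max(a, b, c) + 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            overall_r2(100.0, 50.0, 50.0)


class TestClassifyFit:
    @pytest.mark.parametrize("value,label", [
        (69.9, "VG"), (60.0, "VG"), (59.99, "G"), (40.0, "G"),
        (39.9, "F"), (19.0, "F"), (18.9, "BF"),
    ])
    def test_thresholds(self, value, label):
        assert classify_fit(value) == label


class TestFitEpisode:
    def test_noiseless_roundtrip_recovers_model(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model, NoiseModel(sigma=0.0),
                                     seed=0)
        result = fit_episode(data, FitConfig())
        for band, true_scale in three_cycle_model.band_scales.items():
            assert result.model.band_scales[band] == pytest.approx(
                true_scale, rel=0.01)
        est = np.array(result.model.plan.switchover_times)
        true = np.array(three_cycle_model.plan.switchover_times)
        assert est.size == true.size
        assert np.max(np.abs(est - true)) <= 2.0 + 1e-9
        assert all(v > 99.9 for v in result.r2.values())
        assert result.ta_count == 3
        assert result.converged

    def test_residuals_vanish_on_noiseless_data(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model, NoiseModel(sigma=0.0),
                                     seed=0)
        result = fit_episode(data, FitConfig())
        for band in ("delta", "sigma", "beta"):
            assert np.nanmax(np.abs(result.residuals[band])) < 1e-6

    def test_noisy_switchover_recovery_rate(self, three_cycle_model):
        true = np.array(three_cycle_model.plan.switchover_times)
        hits = 0
        for seed in range(100):
            data = generate_episode_data(three_cycle_model,
                                         NoiseModel(sigma=0.1), seed=seed)
            result = fit_episode(data, FitConfig())
            est = np.array(result.model.plan.switchover_times)
            if est.size == true.size and np.max(np.abs(est - true)) <= 4.0 + 1e-9:
                hits += 1
        assert hits >= 90  # within +/-2 bins in at least 90% of replicates

    def test_missing_bins_do_not_affect_result(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model, NoiseModel(sigma=0.05),
                                     seed=1)
        bands = {k: v.copy() for k, v in data.bands.items()}
        bands["delta"][7] = np.nan
        bands["sigma"][30] = np.nan
        masked = PowerTimeCourse(time=data.time, bands=bands)
        r1 = fit_episode(masked, FitConfig())
        # replacing a missing bin's hidden value changes nothing
        bands2 = {k: v.copy() for k, v in bands.items()}
        r2 = fit_episode(PowerTimeCourse(time=data.time, bands=bands2),
                         FitConfig())
        assert r1.model.plan.switchover_times == r2.model.plan.switchover_times
        assert r1.r2_overall == pytest.approx(r2.r2_overall, rel=1e-12)

    def test_beta_bias_subtraction_roundtrip(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model, NoiseModel(sigma=0.0),
                                     seed=0)
        result = fit_episode(data, FitConfig(beta_bias=2.0))
        assert result.model.beta_bias == 2.0
        assert result.model.band_scales["beta"] == pytest.approx(5.0, rel=0.01)

    def test_free_probabilities_do_not_materially_improve_fit(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model, NoiseModel(sigma=0.1),
                                     seed=5)
        fixed = fit_episode(data, FitConfig())
        free = fit_episode(data, FitConfig(free_probabilities=True))
        # freeing the probability vector cannot buy a meaningfully better fit
        assert free.r2_overall <= fixed.r2_overall + 5.0
        p = np.array(free.model.probabilities.as_vector())
        assert np.all(p > 0) and np.all(p < 1)

    def test_delta_required(self):
        tc = PowerTimeCourse(time=np.arange(50) * 2.0 + 1.0,
                             bands={"sigma": np.ones(50)})
        with pytest.raises(ValueError):
            fit_episode(tc, FitConfig())

    def test_runs_test_reported_on_noisy_fit(self, three_cycle_model):
        data = generate_episode_data(three_cycle_model, NoiseModel(sigma=0.1),
                                     seed=2)
        result = fit_episode(data, FitConfig())
        assert result.runs_test_p is None or 0.0 <= result.runs_test_p <= 1.0
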