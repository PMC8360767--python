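import numpy as np
import pandas as pd
import pytest

from oscivm import behavior_osc as bo
from oscivm import synthetic_data as synth
from oscivm.exceptions import InputError, SingularFitError


def trials_from(delays_ms, correct, subject="s1"):
    return pd.DataFrame(
        {"subject_id": subject, "delay_ms": delays_ms, "correct": correct}
    )


def series_from_function(fn, n_bins=30, width_ms=20.0):
    centers = (np.arange(n_bins) + 0.5) * width_ms / 1000.0
    return bo.AccuracySeries(
        bin_center_s=centers, prop_correct=fn(centers),
        n_trials=np.full(n_bins, 100), bin_width_s=width_ms / 1000.0,
    )


class TestBinAccuracy:
    def test_all_correct(self):
        t = trials_from([5, 100, 250, 590], [1, 1, 1, 1])
        s = bo.bin_accuracy(t)
        assert np.all(s.prop_correct == 1.0)

    def test_30_bins_for_default_range(self):
        rng = np.random.default_rng(0)
        t = trials_from(rng.integers(0, 61, 4000) * 10, rng.integers(0, 2, 4000))
        s = bo.bin_accuracy(t)
        assert s.bin_center_s.size + s.n_empty_bins == 30
        assert s.n_empty_bins == 0

    def test_hand_counted_bins(self):
        t = trials_from([5, 15, 25, 25, 35, 45], [1, 1, 0, 1, 1, 0])
        s = bo.bin_accuracy(t, bin_width_ms=20, delay_min_ms=0, delay_max_ms=600)
        np.testing.assert_allclose(s.prop_correct[:3], [1.0, 2 / 3, 0.0])
        np.testing.assert_array_equal(s.n_trials[:3], [2, 3, 1])
        np.testing.assert_allclose(s.bin_center_s[:3], [0.010, 0.030, 0.050])

    def test_max_delay_joins_last_bin(self):
        t = trials_from([600.0, 590.0], [1, 1])
        s = bo.bin_accuracy(t)
        assert s.bin_center_s.size == 1
        assert s.n_trials[0] == 2

    def test_empty_table(self):
        with pytest.raises(InputError):
            bo.bin_accuracy(trials_from([], []))

    def test_width_must_divide_range(self):
        with pytest.raises(InputError):
            bo.bin_accuracy(trials_from([10], [1]), bin_width_ms=70)


class TestFitSinusoid:
    def test_constant_series(self):
        s = series_from_function(lambda x: np.full_like(x, 0.8))
        fit = bo.fit_sinusoid_at_frequency(s, 5.0)
        assert fit.beta0 == pytest.approx(0.8, abs=1e-12)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.beta2 == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == 0.0

    def test_exact_interpolation_at_5hz(self):
        s = series_from_function(lambda x: 0.7 + 0.1 * np.sin(2 * np.pi * 5 * x))
        fit = bo.fit_sinusoid_at_frequency(s, 5.0)
        assert fit.beta0 == pytest.approx(0.7, abs=1e-10)
        assert fit.beta1 == pytest.approx(0.1, abs=1e-10)
        assert fit.beta2 == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_ols_matches_brute_force_grid(self):
        # independent oracle: exhaustive search over (amplitude, phase) with
        # the optimal intercept in closed form
        rng = np.random.default_rng(42)
        s = series_from_function(
            lambda x: 0.7 + 0.08 * np.sin(2 * np.pi * 6 * x + 1.1)
        )
        s.prop_correct = s.prop_correct + rng.normal(0, 0.02, s.prop_correct.size)
        f = 6.0
        x, y = s.bin_center_s, s.prop_correct
        amps = np.linspace(0, 0.5, 600)
        phases = np.linspace(0, 2 * np.pi, 628, endpoint=False)
        best = (np.inf, None, None)
        for a in amps:
            pred = a * np.sin(2 * np.pi * f * x[None, :] + phases[:, None])
            b0 = (y[None, :] - pred).mean(axis=1)
            ss = np.sum((y[None, :] - pred - b0[:, None]) ** 2, axis=1)
            j = int(np.argmin(ss))
            if ss[j] < best[0]:
                best = (ss[j], a, phases[j])
        fit = bo.fit_sinusoid_at_frequency(s, f)
        ss_ols = np.sum((y - fit.predict(x)) ** 2)
        assert ss_ols <= best[0] + 1e-9
        assert abs(fit.amplitude - best[1]) <= amps[1] - amps[0] + 1e-9
        dphi = np.angle(np.exp(1j * (fit.phase_rad - best[2])))
        assert abs(dphi) <= phases[1] - phases[0] + 1e-9

    def test_aliasing_frequency_is_singular(self):
        # f = 1/bin_width: sin/cos constant across bin centers
        s = series_from_function(lambda x: np.full_like(x, 0.7))
        with pytest.raises(SingularFitError, match="50"):
            bo.fit_sinusoid_at_frequency(s, 50.0)

    def test_too_few_bins(self):
        s = series_from_function(lambda x: x, n_bins=3)
        with pytest.raises(InputError):
            bo.fit_sinusoid_at_frequency(s, 5.0)

    def test_r2_affine_invariance(self):
        rng = np.random.default_rng(1)
        s = series_from_function(lambda x: 0.6 + 0.1 * np.sin(2 * np.pi * 4 * x))
        s.prop_correct = s.prop_correct + rng.normal(0, 0.03, 30)
        r2_a = bo.fit_sinusoid_at_frequency(s, 4.0).r_squared
        s.prop_correct = 2.5 * s.prop_correct - 0.3
        r2_b = bo.fit_sinusoid_at_frequency(s, 4.0).r_squared
        assert r2_a == pytest.approx(r2_b, abs=1e-10)

    def test_amplitude_phase_identity(self):
        s = series_from_function(lambda x: 0.7 + 0.1 * np.sin(2 * np.pi * 5 * x + 0.8))
        fit = bo.fit_sinusoid_at_frequency(s, 5.0)
        x = s.bin_center_s
        w = 2 * np.pi * 5.0 * x
        lhs = fit.beta1 * np.sin(w) + fit.beta2 * np.cos(w)
        rhs = fit.amplitude * np.sin(w + fit.phase_rad)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestScanFrequencyGrid:
    def test_default_grid_has_181_frequencies(self):
        s = series_from_function(lambda x: 0.7 + 0.1 * np.sin(2 * np.pi * 5 * x))
        _, spectrum = bo.scan_frequency_grid(s)
        assert spectrum.shape[0] == 181

    def test_noiseless_recovery_on_grid(self):
        s = series_from_function(lambda x: 0.7 + 0.1 * np.sin(2 * np.pi * 5.4 * x))
        best, _ = bo.scan_frequency_grid(s)
        assert best.freq_hz == pytest.approx(5.4, abs=1e-9)

    def test_constant_series_tie_goes_to_fmin(self):
        s = series_from_function(lambda x: np.full_like(x, 0.75))
        best, spectrum = bo.scan_frequency_grid(s)
        assert best.freq_hz == pytest.approx(2.0)
        finite = spectrum[np.isfinite(spectrum[:, 1]), 1]
        np.testing.assert_allclose(finite, 0.0, atol=1e-12)

    def test_scan_equals_per_frequency_ols(self):
        rng = np.random.default_rng(2)
        s = series_from_function(lambda x: 0.7 + 0.05 * np.sin(2 * np.pi * 7.3 * x))
        s.prop_correct = s.prop_correct + rng.normal(0, 0.02, 30)
        best, spectrum = bo.scan_frequency_grid(s, 2.0, 20.0, 0.5)
        for f, r2 in spectrum:
            if np.isfinite(r2):
                assert r2 == pytest.approx(
                    bo.fit_sinusoid_at_frequency(s, f).r_squared, abs=1e-12
                )
        assert best.r_squared == np.nanmax(spectrum[:, 1])


class TestPermutation:
    def test_add_one_rule_floor(self):
        cfg = synth.GeneratorConfig(seed=21, n_trials=5000, osc_amp=0.25,
                                    baseline_acc=0.7)
        trials = synth.gen_behavior_trials(cfg)
        res = bo.permutation_corrected_pvalue(trials, n_perm=999, seed=0)
        assert res.p_corrected == pytest.approx(1 / 1000)
        assert res.above_95th_percentile

    def test_degenerate_all_correct(self):
        trials = trials_from(np.arange(0, 600, 2.0), np.ones(300, dtype=int))
        with pytest.warns(UserWarning, match="degenerate"):
            res = bo.permutation_corrected_pvalue(trials, n_perm=100, seed=0)
        assert res.p_corrected == 1.0

    def test_nperm_floor(self):
        trials = trials_from([0, 10, 20, 30] * 30, [1, 0] * 60)
        with pytest.raises(InputError):
            bo.permutation_corrected_pvalue(trials, n_perm=10)

    def test_fast_null_equals_naive_rescan(self):
        # re-derive the null with the identical shuffle stream, but via the
        # plain bin + grid-scan route
        cfg = synth.GeneratorConfig(seed=22, n_trials=400)
        trials = synth.gen_behavior_trials(cfg)
        n_perm, seed = 60, 7
        res = bo.permutation_corrected_pvalue(
            trials, n_perm=max(n_perm, 100), seed=seed, step=1.0
        )
        rng = np.random.default_rng(seed)
        perm = trials["correct"].to_numpy(dtype=float).copy()
        naive = []
        for _ in range(max(n_perm, 100)):
            rng.shuffle(perm)
            shuffled = trials.copy()
            shuffled["correct"] = perm
            s = bo.bin_accuracy(shuffled)
            best, _ = bo.scan_frequency_grid(s, 2.0, 20.0, 1.0)
            naive.append(best.r_squared)
        np.testing.assert_allclose(res.null_max_r2, naive, atol=1e-10)

    def test_null_calibration_small(self):
        # rough super-uniformity check at desk scale (full version: acceptance)
        rejections = 0
        n_sets = 40
        for i in range(n_sets):
            cfg = synth.GeneratorConfig(seed=3000 + i, n_trials=600, osc_amp=0.0)
            trials = synth.gen_behavior_trials(cfg)
            res = bo.permutation_corrected_pvalue(trials, n_perm=199, seed=i)
            rejections += res.p_corrected < 0.05
        assert rejections / n_sets <= 0.15


class TestSubjectSineGlm:
    def test_null_betas_near_zero(self):
        cfg = synth.GeneratorConfig(seed=23, n_trials=20_000, osc_amp=0.0)
        trials = synth.gen_behavior_trials(cfg)
        b_sin, b_cos = bo.subject_sine_glm(trials, 5.4)
        se = np.sqrt(0.7 * 0.3 / 20_000) * np.sqrt(2)
        assert abs(b_sin) < 3 * se
        assert abs(b_cos) < 3 * se

    def test_deterministic_threshold_outcomes(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 600, 5000)
        y = (np.sin(2 * np.pi * 5.0 * d / 1000.0) > 0).astype(int)
        b_sin, b_cos = bo.subject_sine_glm(trials_from(d, y), 5.0)
        assert b_sin > 0.3
        assert abs(b_cos) < 0.05

    def test_agreement_with_binned_fit(self):
        cfg = synth.GeneratorConfig(seed=24, n_trials=60_000, osc_amp=0.1,
                                    osc_freq_hz=5.4)
        trials = synth.gen_behavior_trials(cfg)
        b_sin, b_cos = bo.subject_sine_glm(trials, 5.4)
        fit = bo.fit_sinusoid_at_frequency(bo.bin_accuracy(trials), 5.4)
        assert b_sin == pytest.approx(fit.beta1, abs=0.02)
        assert b_cos == pytest.approx(fit.beta2, abs=0.02)

    def test_minimum_trials(self):
        with pytest.raises(InputError):
            bo.subject_sine_glm(trials_from([1, 2, 3], [1, 0, 1]), 5.0)


class TestHotelling:
    def test_zero_mean_gives_zero_t2(self):
        pairs = np.array([[0.3, 0.1], [-0.3, -0.1], [0.1, -0.2], [-0.1, 0.2]])
        res = bo.hotelling_t2_test(pairs)
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_t2(self):
        # independent oracle: explicit 2x2 inverse of the sample covariance
        pairs = np.array([[1.0, 0.0], [1.2, 0.1], [0.8, -0.1], [1.0, 0.05]])
        n = 4
        mean = pairs.mean(axis=0)
        dev = pairs - mean
        s11 = np.sum(dev[:, 0] ** 2) / (n - 1)
        s22 = np.sum(dev[:, 1] ** 2) / (n - 1)
        s12 = np.sum(dev[:, 0] * dev[:, 1]) / (n - 1)
        det = s11 * s22 - s12 ** 2
        quad = (mean[0] ** 2 * s22 - 2 * mean[0] * mean[1] * s12
                + mean[1] ** 2 * s11) / det
        expected_t2 = n * quad
        res = bo.hotelling_t2_test(pairs)
        assert res.t2 == pytest.approx(expected_t2, abs=1e-9)
        assert res.df == (2, 2)

    def test_singular_covariance_errors(self):
        # the spec's literal 4-pair example: deviations are collinear
        pairs = np.array([[1.0, 0.0], [1.2, 0.1], [0.8, -0.1], [1.0, 0.0]])
        with pytest.raises(SingularFitError):
            bo.hotelling_t2_test(pairs)

    def test_needs_three_subjects(self):
        with pytest.raises(InputError):
            bo.hotelling_t2_test(np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_type_one_calibration(self, rng):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            pairs = rng.normal(size=(7, 2))
            rejections += bo.hotelling_t2_test(pairs).p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestFrequencyRecoveryProperty:
    def test_median_error_within_grid_tolerance(self):
        errors = []
        for seed in range(20):
            cfg = synth.GeneratorConfig(seed=400 + seed, n_trials=7000,
                                        osc_amp=0.1, osc_freq_hz=5.4)
            trials = synth.gen_behavior_trials(cfg)
            best, _ = bo.scan_frequency_grid(bo.bin_accuracy(trials))
            errors.append(abs(best.freq_hz - 5.4))
        assert np.median(errors) <= 0.3
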