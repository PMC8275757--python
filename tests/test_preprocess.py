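import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilkit.errors import ConfigError, DataError
from pupilkit.preprocess import (
    FWHM_TO_SIGMA,
    detect_loss_segments,
    epoch_and_baseline,
    gaussian_kernel_radius,
    interpolate_loss,
    moving_average,
    preprocess_run,
    zscore_run,
)

from conftest import make_events, make_run


# ---------------------------------------------------------------------------
# oracle: the literal convolution chain
# ---------------------------------------------------------------------------


def convolution_oracle(flags, sampling_rate, fwhm_ms=200.0):
    """Binary vector -> truncated-Gaussian convolution -> ceil -> diff."""
    flags = np.asarray(flags, dtype=float)
    sigma = (fwhm_ms / FWHM_TO_SIGMA) / 1000.0 * sampling_rate
    radius = int(np.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel /= kernel.sum()
    # centred slice of the full convolution ('same' misbehaves when the
    # kernel is longer than the signal)
    smoothed = np.convolve(flags, kernel, mode="full")[radius : radius + flags.size]
    boxcar = np.ceil(np.minimum(smoothed, 1.0))
    d = np.diff(np.concatenate(([0.0], boxcar, [0.0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


class TestDetectLossSegments:
    def test_all_false_gives_empty_list(self):
        assert detect_loss_segments(np.zeros(1000, bool), 500.0) == []

    def test_all_true_gives_whole_run(self):
        assert detect_loss_segments(np.ones(50, bool), 500.0) == [(0, 50)]

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ConfigError):
            detect_loss_segments(np.zeros(10, bool), 500.0, fwhm_ms=0.0)

    def test_single_sample_spans_kernel_radius(self):
        # one true sample at k -> segment k +- ceil(3 sigma fs) samples
        fs, k, n = 500.0, 600, 1200
        flags = np.zeros(n, bool)
        flags[k] = True
        radius = gaussian_kernel_radius(fs, 200.0)
        sigma_samples = (200.0 / FWHM_TO_SIGMA) / 1000.0 * fs
        assert radius == int(np.ceil(3 * sigma_samples))
        segs = detect_loss_segments(flags, fs)
        assert segs == [(k - radius, k + radius + 1)]
        assert segs == convolution_oracle(flags, fs)

    def test_narrow_gap_merges_to_one_segment(self):
        fs = 500.0
        radius = gaussian_kernel_radius(fs, 200.0)
        flags = np.zeros(3000, bool)
        flags[1000:1010] = True
        flags[1010 + radius : 1020 + radius] = True  # gap < kernel support
        segs = detect_loss_segments(flags, fs)
        assert len(segs) == 1
        assert segs == convolution_oracle(flags, fs)

    def test_wide_gap_stays_two_segments(self):
        fs = 500.0
        radius = gaussian_kernel_radius(fs, 200.0)
        flags = np.zeros(5000, bool)
        flags[500:510] = True
        flags[510 + 2 * radius + 100 : 520 + 2 * radius + 100] = True
        segs = detect_loss_segments(flags, fs)
        assert len(segs) == 2
        assert segs == convolution_oracle(flags, fs)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_convolution_oracle_on_random_masks(self, data):
        n = data.draw(st.integers(200, 1500))
        fs = data.draw(st.sampled_from([100.0, 250.0, 500.0]))
        fwhm = data.draw(st.sampled_from([50.0, 100.0, 200.0]))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        flags = rng.random(n) < 0.02
        if flags.all() or not flags.any():
            return
        assert detect_loss_segments(flags, fs, fwhm) == convolution_oracle(
            flags, fs, fwhm
        )


class TestInterpolateLoss:
    def test_linear_signal_reconstructed_exactly(self):
        y = 3.0 + 0.25 * np.arange(2000)
        run = make_run(y.copy())
        run.diameter[800:900] = np.nan
        run.loss_flags[800:900] = True
        segs = detect_loss_segments(run.loss_flags, run.sampling_rate)
        out = interpolate_loss(run, segs)
        np.testing.assert_allclose(out.diameter, y, atol=1e-9)

    def test_gap_at_run_start_constant_fill(self):
        y = np.full(500, 7.0)
        y[200:] = np.linspace(7.0, 9.0, 300)
        run = make_run(y.copy())
        run.diameter[:50] = np.nan
        run.loss_flags[:50] = True
        out = interpolate_loss(run, [(0, 50)])
        np.testing.assert_array_equal(out.diameter[:50], np.full(50, y[50]))

    def test_loss_flags_preserved_for_audit(self):
        run = make_run(np.ones(300))
        run.diameter[100:120] = np.nan
        run.loss_flags[100:120] = True
        out = interpolate_loss(run, [(100, 120)])
        assert out.loss_flags[100:120].all()

    def test_sinusoid_error_within_second_derivative_bound(self):
        # linear interpolation error <= max|f''| * h^2 / 8 over a gap of width h
        fs, f, amp = 500.0, 2.0, 1.0
        t = np.arange(5000) / fs
        y = amp * np.sin(2 * np.pi * f * t)
        run = make_run(y.copy(), sampling_rate=fs)
        gap = (2000, 2100)  # 200 ms
        run.diameter[gap[0] : gap[1]] = np.nan
        run.loss_flags[gap[0] : gap[1]] = True
        out = interpolate_loss(run, [gap])
        h = (gap[1] - gap[0] + 1) / fs
        bound = (2 * np.pi * f) ** 2 * amp * h**2 / 8.0
        err = np.max(np.abs(out.diameter[gap[0] : gap[1]] - y[gap[0] : gap[1]]))
        assert err <= bound

    def test_no_valid_samples_raises(self):
        run = make_run(np.full(100, np.nan), loss=np.ones(100, bool))
        with pytest.raises(DataError):
            interpolate_loss(run, [(0, 100)])


class TestZscoreRun:
    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        run = make_run(5.0 + rng.normal(0, 2, 5000))
        out = zscore_run(run)
        assert abs(out.diameter.mean()) < 1e-12
        assert abs(out.diameter.std() - 1.0) < 1e-12
        assert out.standardized and out.units_label == "z"

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 2000)
        z1 = zscore_run(make_run(x)).diameter
        z2 = zscore_run(make_run(3.7 * x + 11.0)).diameter
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_permutation_of_samples_permutes_z_values(self):
        # whole-run moments: z-scoring commutes with any sample reordering
        rng = np.random.default_rng(2)
        x = rng.normal(3, 2, 1000)
        perm = rng.permutation(1000)
        z = zscore_run(make_run(x)).diameter
        z_perm = zscore_run(make_run(x[perm])).diameter
        np.testing.assert_allclose(z_perm, z[perm], atol=1e-12)
        # brute-force moments
        np.testing.assert_allclose(z, (x - x.mean()) / x.std(), atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            zscore_run(make_run(np.full(100, 4.2)))

    def test_sentinels_rejected(self):
        run = make_run(np.ones(100))
        run.diameter[5] = np.nan
        run.loss_flags[5] = True
        with pytest.raises(DataError):
            zscore_run(run)


class TestEpochAndBaseline:
    def _run_and_events(self, n_trials=4, fs=500.0):
        rng = np.random.default_rng(3)
        onsets = 2000.0 + np.arange(n_trials) * 12_000.0
        n = int((onsets[-1] + 9000) * fs / 1000)
        run = make_run(rng.normal(0, 1, n), sampling_rate=fs, standardized=True)
        return run, make_events(onsets)

    def test_baseline_mean_is_zero(self):
        run, events = self._run_and_events()
        ep = epoch_and_baseline(run, events)
        bmask = (ep.times_ms >= -500) & (ep.times_ms < 0)
        np.testing.assert_allclose(ep.matrix[:, bmask].mean(axis=1), 0.0, atol=1e-12)

    def test_every_bin_shifted_by_baseline_mean(self):
        run, events = self._run_and_events(n_trials=1)
        raw = epoch_and_baseline(run, events, baseline_ms=(-500.0, 0.0))
        # recompute by hand
        onset = int(round(events["stimulus_onset_ms"][0] * run.sampling_rate / 1000))
        raw_epoch = run.diameter[onset - 250 : onset + 3500]
        m = raw_epoch[:250].mean()
        np.testing.assert_allclose(raw.matrix[0], raw_epoch - m, atol=1e-12)

    def test_default_window_has_3750_bins_at_2ms(self):
        run, events = self._run_and_events()
        ep = epoch_and_baseline(run, events)
        assert ep.n_bins == 3750
        assert ep.bin_width_ms == 2.0

    def test_100_trials_give_100_rows(self):
        run, events = self._run_and_events(n_trials=100)
        assert epoch_and_baseline(run, events).n_trials == 100

    def test_out_of_bounds_epoch_names_trial(self):
        run, events = self._run_and_events(n_trials=2)
        events.loc[1, "stimulus_onset_ms"] = run.t_ms[-1]  # epoch overruns
        with pytest.raises(DataError, match="trial 2"):
            epoch_and_baseline(run, events)

    def test_unstandardized_run_rejected(self):
        run, events = self._run_and_events()
        run.standardized = False
        with pytest.raises(DataError):
            epoch_and_baseline(run, events)

    def test_baseline_correction_commutes_with_per_trial_constant(self):
        run, events = self._run_and_events(n_trials=3)
        ep1 = epoch_and_baseline(run, events)
        # adding a constant across whole trials leaves corrected epochs unchanged
        shifted = run.diameter.copy()
        for t0 in events["stimulus_onset_ms"]:
            i = int(round(t0 * run.sampling_rate / 1000))
            shifted[i - 250 : i + 3500] += 0.7
        run2 = make_run(shifted, sampling_rate=run.sampling_rate, standardized=True)
        ep2 = epoch_and_baseline(run2, events)
        np.testing.assert_allclose(ep1.matrix, ep2.matrix, atol=1e-12)

    def test_1ms_resampling_mode(self):
        run, events = self._run_and_events()
        ep = epoch_and_baseline(run, events, bin_width_ms=1.0)
        assert ep.n_bins == 7500
        assert ep.bin_width_ms == 1.0


class TestMovingAverage:
    def _epochs(self, matrix):
        run = make_run(np.zeros(100), standardized=True)
        from pupilkit.preprocess import TrialEpochs

        m = np.asarray(matrix, float)
        return TrialEpochs(
            participant_id="s",
            matrix=m,
            times_ms=np.arange(m.shape[1]) * 2.0,
            bin_width_ms=2.0,
            window_ms=(0.0, m.shape[1] * 2.0),
            events=make_events([0.0] * m.shape[0]),
            baseline_corrected=True,
        )

    def test_width_one_bin_is_identity(self):
        rng = np.random.default_rng(4)
        m = rng.normal(0, 1, (3, 50))
        out = moving_average(self._epochs(m), width_ms=2.0)
        np.testing.assert_array_equal(out.matrix, m)

    def test_constant_epoch_unchanged(self):
        m = np.full((2, 40), 1.5)
        out = moving_average(self._epochs(m), width_ms=10.0)
        np.testing.assert_allclose(out.matrix, m, atol=1e-12)

    def test_white_noise_variance_reduced_by_width(self):
        rng = np.random.default_rng(5)
        w = 9
        m = rng.normal(0, 1, (200, 3000))
        out = moving_average(self._epochs(m), width_ms=2.0 * w)
        interior = out.matrix[:, w : 3000 - w]
        ratio = interior.var() * w
        assert 0.85 < ratio < 1.15

    def test_width_below_bin_rejected(self):
        with pytest.raises(ConfigError):
            moving_average(self._epochs(np.zeros((1, 10))), width_ms=1.0)


class TestPipelineProperties:
    def test_idempotent_on_lossfree_standardized_run(self):
        rng = np.random.default_rng(6)
        run = zscore_run(make_run(rng.normal(0, 1, 4000)))
        segs = detect_loss_segments(run.loss_flags, run.sampling_rate) if run.loss_flags.any() else []
        out = zscore_run(interpolate_loss(run, segs))
        np.testing.assert_allclose(out.diameter, run.diameter, atol=1e-12)

    def test_preprocess_run_full_chain(self):
        rng = np.random.default_rng(7)
        fs = 500.0
        onsets = 2000.0 + np.arange(3) * 12_000.0
        n = int((onsets[-1] + 9000) * fs / 1000)
        run = make_run(4.0 + rng.normal(0, 0.5, n), sampling_rate=fs)
        run.diameter[5000:5050] = np.nan
        run.loss_flags[5000:5050] = True
        ep = preprocess_run(run, make_events(onsets))
        assert ep.baseline_corrected
        assert np.isfinite(ep.matrix).all()
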