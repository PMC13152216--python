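"""Signal preprocessing, wavelet spectrogram, SOP window, modes, projection."""

import numpy as np
import pytest

import sopdyn as sd
from conftest import plateau_spectrogram
from sopdyn.spectral_embedding import (
    NoTransitionFoundError,
    default_freq_grid,
    delta_alpha_ratio,
)


def band_spectrogram(ratio_by_time, n_seconds=None, value_alpha=1.0):
    """Synthetic spectrogram whose delta/alpha amplitude ratio is prescribed."""
    freqs = default_freq_grid()
    ratio = np.asarray(ratio_by_time, dtype=float)
    t = np.arange(ratio.size, dtype=float)
    amp = np.zeros((freqs.size, ratio.size))
    amp[(freqs >= 8) & (freqs <= 12)] = value_alpha
    amp[(freqs >= 0.5) & (freqs <= 4)] = ratio * value_alpha
    return sd.Spectrogram(freqs=freqs, times=t, amplitudes=amp)


class TestPreprocess:
    def test_passband_amplitude(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        out = sd.preprocess_signal(np.sin(2 * np.pi * 10 * t), fs)
        assert np.abs(out[500:-500]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        out = sd.preprocess_signal(np.sin(2 * np.pi * 50 * t), fs)
        atten_db = 20 * np.log10(np.abs(out[500:-500]).max())
        assert atten_db < -30

    @pytest.mark.parametrize("n", [5000, 5003, 12345])
    def test_output_length(self, n):
        rng = np.random.default_rng(0)
        out = sd.preprocess_signal(rng.standard_normal(n), 500.0)
        assert out.size == round(n * 100 / 500)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="unsupported sampling rate"):
            sd.preprocess_signal(np.zeros(1000), 50.0)

    def test_constant_input_passes_as_zero(self):
        out = sd.preprocess_signal(np.full(5000, 3.3), 500.0)
        assert np.abs(out).max() < 1e-6


class TestWaveletSpectrogram:
    def test_grid_shape_and_span(self):
        spec = sd.wavelet_spectrogram(np.random.default_rng(1).standard_normal(2000))
        assert spec.amplitudes.shape == (200, 2000)
        assert spec.freqs[0] == 0.5 and spec.freqs[-1] == 20.0
        assert np.allclose(np.diff(spec.freqs), spec.freqs[1] - spec.freqs[0])

    def test_pure_tone_peak_frequency(self):
        """A 10 Hz tone peaks at the 10 Hz bin (mean spectrum) and within two
        bins per column (amplitude ripple of the analytic wavelet)."""
        sig = np.sin(2 * np.pi * 10 * np.arange(3000) / 100)
        spec = sd.wavelet_spectrogram(sig)
        binw = spec.freqs[1] - spec.freqs[0]
        mean_peak = spec.freqs[np.argmax(spec.amplitudes[:, 300:2700].mean(axis=1))]
        assert abs(mean_peak - 10.0) <= binw
        per_col = spec.freqs[np.argmax(spec.amplitudes[:, 300:2700], axis=0)]
        assert np.abs(per_col - 10.0).max() <= 2 * binw

    def test_zero_signal_zero_amplitudes(self):
        spec = sd.wavelet_spectrogram(np.zeros(1500))
        assert np.all(spec.amplitudes == 0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            sd.wavelet_spectrogram(np.zeros(500))
        with pytest.raises(ValueError):
            sd.wavelet_spectrogram(np.array([]))


class TestSOPWindow:
    def test_no_transition(self):
        spec = band_spectrogram(np.full(700, 0.5))
        with pytest.raises(NoTransitionFoundError):
            sd.detect_sop_window(spec)

    def test_permanent_switch(self):
        """Ratio stepping 0.5 -> 2.0 at 300 s gives t_start = t_end = 300."""
        ratio = np.where(np.arange(700) < 300, 0.5, 2.0)
        win = sd.detect_sop_window(band_spectrogram(ratio))
        assert win.t_start == 300.0 and win.t_end == 300.0
        assert win.window_start == 100.0 and win.window_end == 500.0

    def test_separate_start_and_end_runs(self):
        """A 90 s flicker block starts the transition; the sustained block ends it."""
        ratio = np.full(900, 0.5)
        ratio[300:391] = 2.0       # > 60 s but < 120 s
        ratio[460:] = 2.0          # sustained
        win = sd.detect_sop_window(band_spectrogram(ratio))
        assert win.t_start == 300.0 and win.t_end == 460.0
        assert (win.window_start, win.window_end) == (100.0, 660.0)

    def test_brute_force_run_scan_agreement(self):
        """Window detection agrees with an independent run-length scan."""
        rng = np.random.default_rng(5)
        ratio = np.where(rng.random(1200) < 0.4, 2.0, 0.5)
        ratio[700:] = 2.0
        spec = band_spectrogram(ratio)
        mask = delta_alpha_ratio(spec) > 1
        # oracle: scan every index for run starts
        def first_run_longer_than(min_len, from_idx=0):
            i = from_idx
            while i < mask.size:
                if mask[i]:
                    j = i
                    while j < mask.size and mask[j]:
                        j += 1
                    if j - i > min_len:
                        return i
                    i = j
                else:
                    i += 1
            return None
        s = first_run_longer_than(60)
        e = first_run_longer_than(120, s)
        win = sd.detect_sop_window(spec)
        assert win.t_start == float(s) and win.t_end == float(e)

    def test_truncation_warns(self):
        ratio = np.where(np.arange(700) < 100, 0.5, 2.0)
        with pytest.warns(UserWarning, match="truncated"):
            win = sd.detect_sop_window(band_spectrogram(ratio))
        assert win.window_start == 0.0

    def test_segments_span_sixty_seconds(self):
        ratio = np.where(np.arange(700) < 300, 0.5, 2.0)
        win = sd.detect_sop_window(band_spectrogram(ratio))
        assert win.wake_segment == (100.0, 160.0)
        assert win.sleep_segment == (440.0, 500.0)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="10 minutes"):
            sd.detect_sop_window(band_spectrogram(np.full(300, 2.0)))


class TestStateModes:
    def make_rank1(self, u_wake, u_sleep, n=700):
        freqs = default_freq_grid()
        amp = np.zeros((freqs.size, n))
        t = np.arange(n, dtype=float)
        amp[:, :200] = np.outer(u_wake, 1.0 + 0.1 * np.cos(t[:200]))
        amp[:, 200:500] = 0.5 * (u_wake + u_sleep)[:, None]
        amp[:, 500:] = np.outer(u_sleep, 1.0 + 0.1 * np.sin(t[500:]))
        spec = sd.Spectrogram(freqs=freqs, times=t, amplitudes=amp)
        win = sd.SOPWindow(t_start=250.0, t_end=350.0, window_start=0.0,
                           window_end=float(n - 1))
        return spec, win

    def test_rank1_segment_recovers_mode(self, synthetic_modes):
        u_w, u_s = synthetic_modes.wake_mode, synthetic_modes.sleep_mode
        spec, win = self.make_rank1(u_w, u_s)
        modes = sd.extract_state_modes(spec, win)
        assert np.abs(modes.wake_mode - u_w).max() < 1e-8
        assert np.abs(modes.sleep_mode - u_s).max() < 1e-8
        assert np.linalg.norm(modes.wake_mode) == pytest.approx(1.0, abs=1e-12)
        assert modes.wake_explained_variance > 0.99
        assert modes.sleep_explained_variance > 0.99

    def test_rank1_with_noise_high_explained_variance(self, synthetic_modes):
        u_w, u_s = synthetic_modes.wake_mode, synthetic_modes.sleep_mode
        spec, win = self.make_rank1(u_w, u_s)
        rng = np.random.default_rng(0)
        amp = spec.amplitudes * (1 + 1e-4 * rng.standard_normal(spec.amplitudes.shape))
        spec = sd.Spectrogram(freqs=spec.freqs, times=spec.times,
                              amplitudes=np.clip(amp, 0, None))
        modes = sd.extract_state_modes(spec, win)
        assert modes.wake_explained_variance > 0.99

    def test_degenerate_segment_rejected(self):
        freqs = default_freq_grid()
        amp = np.zeros((freqs.size, 700))
        amp[:, 500:] = 1.0
        spec = sd.Spectrogram(freqs=freqs, times=np.arange(700.0), amplitudes=amp)
        win = sd.SOPWindow(t_start=250.0, t_end=350.0, window_start=0.0,
                           window_end=699.0)
        with pytest.raises(ValueError, match="wake segment"):
            sd.extract_state_modes(spec, win)


class TestProjection:
    def test_round_trip_exact(self, synthetic_modes):
        spec, win, w = plateau_spectrogram(synthetic_modes)
        emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                      smooth_seconds=0.0, downsample=1)
        assert np.corrcoef(emb.values, w)[0, 1] > 0.999
        rec = sd.reconstruct_spectrogram(emb, synthetic_modes)
        assert np.abs(rec.amplitudes - spec.amplitudes).max() < 1e-6

    def test_pure_mode_columns_map_to_anchors(self, synthetic_modes):
        spec, win, w = plateau_spectrogram(synthetic_modes)
        emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                      smooth_seconds=0.0, downsample=1)
        assert np.allclose(emb.values[spec.times < 10.0], 1.0, atol=1e-9)
        assert np.allclose(emb.values[spec.times > 90.0], -1.0, atol=1e-9)

    def test_affine_anchor_means(self, synthetic_modes):
        spec, win, _ = plateau_spectrogram(synthetic_modes)
        emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                      smooth_seconds=1.0, downsample=2)
        wake = emb.values[(emb.times >= win.wake_segment[0])
                          & (emb.times < win.wake_segment[1])]
        sleep = emb.values[(emb.times >= win.sleep_segment[0])
                           & (emb.times <= win.sleep_segment[1])]
        assert wake.mean() == pytest.approx(1.0, abs=1e-10)
        assert sleep.mean() == pytest.approx(-1.0, abs=1e-10)
        assert wake.mean() > sleep.mean()

    def test_downsample_count(self, synthetic_modes):
        spec, win, _ = plateau_spectrogram(synthetic_modes, n=1000)
        emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                      smooth_seconds=0.0, downsample=10)
        assert len(emb) == 100

    def test_zero_column_skipped_with_warning(self, synthetic_modes):
        spec, win, _ = plateau_spectrogram(synthetic_modes)
        amp = spec.amplitudes.copy()
        amp[:, 500] = 0.0
        spec = sd.Spectrogram(freqs=spec.freqs, times=spec.times, amplitudes=amp)
        with pytest.warns(UserWarning, match="zero-norm"):
            emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                          smooth_seconds=0.0, downsample=1)
        assert len(emb) == spec.times.size - 1


class TestReconstruct:
    @pytest.mark.parametrize("x, weight", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5)])
    def test_state_to_mixture(self, synthetic_modes, x, weight):
        rec = sd.reconstruct_spectrogram(np.array([x]), synthetic_modes)
        expected = (weight * synthetic_modes.wake_mode
                    + (1 - weight) * synthetic_modes.sleep_mode)
        assert np.allclose(rec.amplitudes[:, 0], expected, atol=1e-12)

    def test_clipping_beyond_state_range(self, synthetic_modes):
        rec = sd.reconstruct_spectrogram(np.array([2.5, -3.0]), synthetic_modes)
        assert np.allclose(rec.amplitudes[:, 0], synthetic_modes.wake_mode)
        assert np.allclose(rec.amplitudes[:, 1], synthetic_modes.sleep_mode)


class TestRank2Diagnostic:
    def test_exact_rank2_explained_variance(self, synthetic_modes):
        spec, win, w = plateau_spectrogram(synthetic_modes)
        emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                      smooth_seconds=0.0, downsample=1)
        diag = sd.global_rank2_diagnostic(spec, win, emb)
        assert diag.explained_variance[:2].sum() == pytest.approx(1.0, abs=1e-8)
        assert diag.corr_embedding > 0.9
        assert abs(diag.explained_variance.sum() - 1.0) < 1e-8

    def test_power_tracking(self, synthetic_modes):
        spec, win, w = plateau_spectrogram(synthetic_modes)
        scale = 1.0 + 0.3 * np.sin(spec.times / 7.0)
        spec = sd.Spectrogram(freqs=spec.freqs, times=spec.times,
                              amplitudes=spec.amplitudes * scale)
        emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                      smooth_seconds=0.0, downsample=1)
        diag = sd.global_rank2_diagnostic(spec, win, emb)
        assert diag.corr_power > 0.9

    def test_constant_input_flagged(self, synthetic_modes):
        freqs = synthetic_modes.freqs
        amp = np.outer(synthetic_modes.wake_mode, np.ones(1001))
        t = np.linspace(0, 100, 1001)
        spec = sd.Spectrogram(freqs=freqs, times=t, amplitudes=amp)
        win = sd.SOPWindow(t_start=40.0, t_end=60.0, window_start=0.0,
                           window_end=100.0, segment_seconds=10.0)
        emb = sd.ObservedEmbedding(values=np.ones(1001), times=t, step_seconds=0.1)
        with pytest.warns(UserWarning, match="zero-variance"):
            diag = sd.global_rank2_diagnostic(spec, win, emb)
        assert np.isnan(diag.corr_embedding)


class TestEndToEndEmbedding:
    def test_wake_sleep_separation_on_synthetic_subjects(self, synthetic_modes):
        """The wake-segment mean exceeds the sleep-segment mean for every subject."""
        for seed in range(4):
            params = sd.ModelParams(alpha=0.3, t0=50.0, sigma=0.4,
                                    sigma_obs=1e-5, dt=0.1)
            sub = sd.synthetic_embedding(params, n_obs=1001, x0=1.0, seed=seed)
            spec = sd.synthetic_spectrogram(sub, synthetic_modes,
                                            power_noise=0.02, seed=seed)
            win = sd.SOPWindow(t_start=40.0, t_end=60.0, window_start=0.0,
                               window_end=100.0, segment_seconds=10.0)
            emb = sd.project_to_embedding(spec, win, synthetic_modes,
                                          smooth_seconds=0.5, downsample=10)
            wake = emb.values[emb.times < 10.0]
            sleep = emb.values[emb.times > 90.0]
            assert wake.mean() > sleep.mean()
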