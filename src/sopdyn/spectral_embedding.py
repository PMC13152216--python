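"""From single-channel EEG to the 1-D sleep-onset transition coordinate.

Pipeline: band-pass + resample the raw signal, complex-Morlet wavelet
spectrogram (200 frequencies in [0.5, 20] Hz), detection of the sleep-onset
period (SOP) window from the delta/alpha amplitude ratio, leading SVD modes
of the wake and sleep segments, and projection of the row-normalized
spectrogram onto (wake_mode - sleep_mode) to obtain the transition
coordinate mu(t) on the model's [-1, +1] state scale.  The inverse map
reconstructs a low-rank spectrogram from a state trajectory by linear
interpolation between the two modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

__all__ = [
    "Spectrogram",
    "SOPWindow",
    "SpectralModes",
    "ObservedEmbedding",
    "SVDDiagnostic",
    "NoTransitionFoundError",
    "TARGET_FS",
    "N_FREQ_BINS",
    "FREQ_RANGE",
    "DELTA_BAND",
    "ALPHA_BAND",
    "preprocess_signal",
    "wavelet_spectrogram",
    "default_freq_grid",
    "detect_sop_window",
    "extract_state_modes",
    "project_to_embedding",
    "reconstruct_spectrogram",
    "global_rank2_diagnostic",
    "load_eeg",
]

TARGET_FS = 100.0          # Hz, working sampling rate after preprocessing
N_FREQ_BINS = 200          # equally spaced frequency bins
FREQ_RANGE = (0.5, 20.0)   # Hz
BANDPASS = (0.5, 30.0)     # Hz, anti-alias / artifact band-pass
DELTA_BAND = (0.5, 4.0)    # Hz
ALPHA_BAND = (8.0, 12.0)   # Hz
MORLET_WAVELET = "cmor1.0-1.5"  # bandwidth 1, center frequency 1.5
WINDOW_PAD_S = 200.0       # seconds added on each side of the transition
SEGMENT_LEN_S = 60.0       # wake/sleep anchor segment length, seconds


class NoTransitionFoundError(RuntimeError):
    """No delta/alpha ratio run qualifies as a wake-to-sleep transition."""


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency amplitude matrix (rows = frequencies, columns = time)."""

    freqs: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if a.shape != (f.size, t.size):
            raise ValueError("amplitudes must have shape (len(freqs), len(times))")
        if np.any(np.diff(f) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("freqs and times must be strictly increasing")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("amplitudes must be finite and non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan

    def column_slice(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Boolean mask of columns with time in the half-open [t_lo, t_hi)."""
        return (self.times >= t_lo) & (self.times < t_hi)


@dataclass(frozen=True)
class SOPWindow:
    """The sleep-onset-period analysis window around the detected transition.

    The window spans [t_start - 200 s, t_end + 200 s] (truncated to the
    recording with a warning); the wake anchor segment is its first 60 s and
    the sleep anchor segment its last 60 s.
    """

    t_start: float
    t_end: float
    window_start: float
    window_end: float
    segment_seconds: float = SEGMENT_LEN_S

    def __post_init__(self) -> None:
        if not (self.window_start < self.t_start <= self.t_end < self.window_end):
            raise ValueError("require window_start < t_start <= t_end < window_end")
        if self.wake_segment[1] > self.sleep_segment[0]:
            raise ValueError("wake and sleep segments overlap; window too short")

    @property
    def wake_segment(self) -> Tuple[float, float]:
        return (self.window_start, self.window_start + self.segment_seconds)

    @property
    def sleep_segment(self) -> Tuple[float, float]:
        return (self.window_end - self.segment_seconds, self.window_end)


@dataclass(frozen=True)
class SpectralModes:
    """Leading wake/sleep spectral SVD modes (unit-norm, sign: entry sum > 0)."""

    wake_mode: np.ndarray
    sleep_mode: np.ndarray
    freqs: np.ndarray
    sign_convention: str = "entry-sum-positive"
    wake_explained_variance: float = np.nan
    sleep_explained_variance: float = np.nan

    def __post_init__(self) -> None:
        w = np.asarray(self.wake_mode, dtype=float)
        s = np.asarray(self.sleep_mode, dtype=float)
        f = np.asarray(self.freqs, dtype=float)
        if w.shape != s.shape or w.shape != f.shape:
            raise ValueError("modes and freqs must share one shape")
        for name, v in (("wake_mode", w), ("sleep_mode", s)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-10:
                raise ValueError(f"{name} must have unit Euclidean norm")
        if float(w @ s) > 1.0 - 1e-6:
            raise ValueError("wake and sleep modes are indistinguishable")
        object.__setattr__(self, "wake_mode", w)
        object.__setattr__(self, "sleep_mode", s)
        object.__setattr__(self, "freqs", f)


@dataclass(frozen=True)
class ObservedEmbedding:
    """The 1-D transition coordinate mu_i with its sampling metadata.

    ``values`` live on the model's state scale (wake-segment mean anchored to
    +1, sleep-segment mean to -1).  ``scaling`` records the affine map
    (center, half-range) applied to the raw projection.
    """

    values: np.ndarray
    times: np.ndarray
    step_seconds: float
    modes: Optional[SpectralModes] = field(default=None, compare=False)
    scaling: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.shape != t.shape or v.ndim != 1:
            raise ValueError("values and times must be 1-D arrays of equal length")
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.values.size

    def to_text(self, path_or_buf) -> None:
        np.savetxt(path_or_buf, np.column_stack([self.times, self.values]),
                   delimiter="\t", header="time_s\tmu", comments="")

    @classmethod
    def from_text(cls, path_or_buf) -> "ObservedEmbedding":
        data = np.loadtxt(path_or_buf, delimiter="\t", skiprows=1, ndmin=2)
        t, v = data[:, 0], data[:, 1]
        step = float(np.median(np.diff(t))) if t.size > 1 else np.nan
        return cls(values=v, times=t, step_seconds=step)


@dataclass(frozen=True)
class SVDDiagnostic:
    """Rank-2 SVD diagnostic of the full SOP-window spectrogram.

    ``corr_power`` is |corr| of the leading temporal mode with per-column
    total amplitude; ``corr_embedding`` is |corr| of the second temporal mode
    with the transition coordinate (absolute values: singular-vector signs
    are arbitrary).  Either is NaN when the paired series has zero variance.
    """

    singular_values: np.ndarray
    leading_temporal: np.ndarray
    second_temporal: np.ndarray
    explained_variance: np.ndarray
    corr_power: float = np.nan
    corr_embedding: float = np.nan

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise ValueError("singular values must be non-negative and non-increasing")
        ev = np.asarray(self.explained_variance, dtype=float)
        if abs(ev.sum() - 1.0) > 1e-8:
            raise ValueError("explained_variance must sum to 1")
        object.__setattr__(self, "singular_values", s)
        object.__setattr__(self, "explained_variance", ev)


# ---------------------------------------------------------------------------
# signal preprocessing and spectrogram
# ---------------------------------------------------------------------------

def preprocess_signal(raw: np.ndarray, fs_in: float) -> np.ndarray:
    """Band-pass 0.5-30 Hz (order-4 Butterworth, zero phase) and resample to 100 Hz.

    The zero-phase filter is applied forward-backward (``sosfiltfilt``), so the
    effective magnitude response is the squared order-4 Butterworth.  Output
    length is ``round(n * 100 / fs_in)``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw must be a 1-D array")
    if fs_in < TARGET_FS:
        raise ValueError(f"unsupported sampling rate {fs_in} Hz: need >= {TARGET_FS} Hz")
    sos = sps.butter(4, BANDPASS, btype="bandpass", fs=fs_in, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if raw.size <= padlen:
        raise ValueError(f"signal too short for zero-phase filtering (need > {padlen} samples)")
    filtered = sps.sosfiltfilt(sos, raw)
    n_out = int(round(raw.size * TARGET_FS / fs_in))
    if fs_in == TARGET_FS:
        return filtered
    return sps.resample(filtered, n_out)


def default_freq_grid() -> np.ndarray:
    """The 200 equally spaced analysis frequencies spanning 0.5-20 Hz."""
    return np.linspace(FREQ_RANGE[0], FREQ_RANGE[1], N_FREQ_BINS)


def wavelet_spectrogram(sig: np.ndarray, fs: float = TARGET_FS) -> Spectrogram:
    """Continuous complex-Morlet spectrogram (cmor, bandwidth 1, center 1.5).

    Returns the wavelet modulus evaluated at 200 equally spaced frequencies in
    [0.5, 20] Hz; columns are the signal samples.
    """
    sig = np.asarray(sig, dtype=float)
    if sig.size == 0:
        raise ValueError("empty signal")
    if sig.size < 10 * fs:
        raise ValueError("signal must span at least 10 s")
    freqs = default_freq_grid()
    wavelet = pywt.ContinuousWavelet(MORLET_WAVELET)
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    coefs, _ = pywt.cwt(sig, scales, wavelet, method="fft")
    amplitudes = np.abs(coefs)
    times = np.arange(sig.size) / fs
    return Spectrogram(freqs=freqs, times=times, amplitudes=amplitudes)


# ---------------------------------------------------------------------------
# SOP window detection
# ---------------------------------------------------------------------------

def _band_mean(spec: Spectrogram, band: Tuple[float, float]) -> np.ndarray:
    rows = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not rows.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return spec.amplitudes[rows].mean(axis=0)


def delta_alpha_ratio(spec: Spectrogram) -> np.ndarray:
    """Per-column ratio of mean delta-band to mean alpha-band amplitude."""
    num = _band_mean(spec, DELTA_BAND)
    den = _band_mean(spec, ALPHA_BAND)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.inf)
    ratio[(den == 0) & (num == 0)] = 1.0  # silent columns: no evidence either way
    return ratio


def _runs(mask: np.ndarray):
    """(start, length) pairs of contiguous True runs, in order."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2] - idx[::2]))


def detect_sop_window(spec: Spectrogram,
                      min_start_s: float = 60.0,
                      min_end_s: float = 120.0) -> SOPWindow:
    """Locate the wake-to-sleep transition from the delta/alpha ratio.

    ``t_start`` is the start of the earliest contiguous run with ratio > 1
    lasting more than ``min_start_s`` (one minute); ``t_end`` is the start of
    the earliest such run, searched from ``t_start`` onward, lasting more than
    ``min_end_s`` (two minutes).  The SOP window pads the transition by 200 s
    on each side, truncated to the recording bounds with a warning.
    """
    if spec.times[-1] - spec.times[0] < 600.0:
        raise ValueError("spectrogram must span at least 10 minutes")
    dt = spec.dt
    ratio = delta_alpha_ratio(spec)
    runs = _runs(ratio > 1.0)

    t_start = None
    for start, length in runs:
        if length * dt > min_start_s:
            t_start = spec.times[start]
            start_idx = start
            break
    if t_start is None:
        raise NoTransitionFoundError(
            "no delta/alpha > 1 run longer than one minute")

    t_end = None
    for start, length in runs:
        if start < start_idx:
            continue
        if length * dt > min_end_s:
            t_end = spec.times[start]
            break
    if t_end is None:
        raise NoTransitionFoundError(
            "no delta/alpha > 1 run longer than two minutes after t_start")

    window_start = t_start - WINDOW_PAD_S
    window_end = t_end + WINDOW_PAD_S
    if window_start < spec.times[0] or window_end > spec.times[-1]:
        warnings.warn("SOP window truncated to recording bounds", stacklevel=2)
        window_start = max(window_start, spec.times[0])
        window_end = min(window_end, spec.times[-1])
    return SOPWindow(t_start=t_start, t_end=t_end,
                     window_start=window_start, window_end=window_end)


# ---------------------------------------------------------------------------
# SVD modes and projection
# ---------------------------------------------------------------------------

def _unit_columns(mat: np.ndarray, on_zero: str = "error") -> Tuple[np.ndarray, np.ndarray]:
    """Unit-normalize columns; returns (normalized, keep_mask)."""
    norms = np.linalg.norm(mat, axis=0)
    keep = norms > 0
    if not keep.all():
        if on_zero == "error":
            raise ValueError("segment contains all-zero spectrogram columns")
        warnings.warn(f"skipping {int((~keep).sum())} zero-norm spectrogram columns",
                      stacklevel=3)
    out = mat[:, keep] / norms[keep]
    return out, keep


def _leading_mode(segment: np.ndarray) -> Tuple[np.ndarray, float]:
    """Leading left-singular vector (entry-sum-positive) and its variance share."""
    u, s, _ = np.linalg.svd(segment, full_matrices=False)
    mode = u[:, 0]
    if mode.sum() < 0:
        mode = -mode
    evr = float(s[0] ** 2 / np.sum(s ** 2))
    return mode, evr


def extract_state_modes(spec: Spectrogram, window: SOPWindow) -> SpectralModes:
    """Leading SVD modes of the unit-column-normalized wake/sleep segments."""
    segments = {}
    for name, (lo, hi) in (("wake", window.wake_segment), ("sleep", window.sleep_segment)):
        cols = spec.column_slice(lo, hi)
        if cols.sum() < 10:
            raise ValueError(f"{name} segment has fewer than 10 spectrogram columns")
        sub = spec.amplitudes[:, cols]
        if not np.any(sub):
            raise ValueError(f"{name} segment is all zero")
        segments[name], _ = _unit_columns(sub, on_zero="error")
    wake_mode, wake_evr = _leading_mode(segments["wake"])
    sleep_mode, sleep_evr = _leading_mode(segments["sleep"])
    return SpectralModes(wake_mode=wake_mode, sleep_mode=sleep_mode,
                         freqs=spec.freqs,
                         wake_explained_variance=wake_evr,
                         sleep_explained_variance=sleep_evr)


def project_to_embedding(spec: Spectrogram, window: SOPWindow, modes: SpectralModes,
                         smooth_seconds: float = 1.0,
                         downsample: int = 10) -> ObservedEmbedding:
    """Project the SOP-window spectrogram onto (wake_mode - sleep_mode).

    Each frequency bin (row) of the window submatrix is normalized to unit
    norm, and each column of the normalized matrix is projected onto the
    wake-minus-sleep direction; the series is Gaussian-smoothed
    (``smooth_seconds`` standard deviation), decimated by ``downsample``
    (default 10), and affinely scaled so the wake-segment mean maps to +1 and
    the sleep-segment mean to -1.  Because the row normalization is constant
    in time, the projection is exactly affine in the wake-mixture weight of a
    two-mode spectrogram, so embedding and reconstruction form a consistent
    round trip.  All-zero columns are skipped with a warning; all-zero rows
    carry no signal and are left out of the projection.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    cols = spec.column_slice(window.window_start, window.window_end)
    # include the final column when the window ends exactly at the recording end
    cols |= spec.times == window.window_end
    if not cols.any():
        raise ValueError("SOP window contains no spectrogram columns")
    sub = spec.amplitudes[:, cols]
    times = spec.times[cols]
    col_norms = np.linalg.norm(sub, axis=0)
    keep = col_norms > 0
    if not keep.all():
        warnings.warn(f"skipping {int((~keep).sum())} zero-norm spectrogram columns",
                      stacklevel=2)
        sub = sub[:, keep]
        times = times[keep]
    row_norms = np.linalg.norm(sub, axis=1)
    rows = row_norms > 0
    normalized = sub[rows] / row_norms[rows, None]
    raw = (modes.wake_mode - modes.sleep_mode)[rows] @ normalized

    if smooth_seconds > 0 and times.size > 1:
        dt = float(np.median(np.diff(times)))
        raw = gaussian_filter1d(raw, sigma=smooth_seconds / dt, mode="nearest")
    raw = raw[::downsample]
    times = times[::downsample]
    step = float(np.median(np.diff(times))) if times.size > 1 else np.nan

    wake = (times >= window.wake_segment[0]) & (times < window.wake_segment[1])
    sleep = (times >= window.sleep_segment[0]) & (times <= window.sleep_segment[1])
    if not wake.any() or not sleep.any():
        raise ValueError("wake or sleep segment contains no embedding samples")
    a_w, a_s = float(raw[wake].mean()), float(raw[sleep].mean())
    if a_w <= a_s:
        raise ValueError("wake-segment projection does not exceed sleep-segment "
                         "projection; modes do not separate the segments")
    center, half = 0.5 * (a_w + a_s), 0.5 * (a_w - a_s)
    values = (raw - center) / half
    return ObservedEmbedding(values=values, times=times, step_seconds=step,
                             modes=modes, scaling=(center, half))


def reconstruct_spectrogram(embedding: Union[ObservedEmbedding, np.ndarray],
                            modes: SpectralModes,
                            times: Optional[np.ndarray] = None) -> Spectrogram:
    """Low-rank spectrogram w * wake_mode + (1 - w) * sleep_mode from states.

    State values on the model scale [-1, +1] are mapped to mixture weights
    ``w = (x + 1) / 2`` and clipped to [0, 1].
    """
    if isinstance(embedding, ObservedEmbedding):
        x = embedding.values
        times = embedding.times if times is None else np.asarray(times, dtype=float)
    else:
        x = np.asarray(embedding, dtype=float)
        times = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    w = np.clip((x + 1.0) / 2.0, 0.0, 1.0)
    amplitudes = np.outer(modes.wake_mode, w) + np.outer(modes.sleep_mode, 1.0 - w)
    return Spectrogram(freqs=modes.freqs, times=times, amplitudes=amplitudes)


def global_rank2_diagnostic(spec: Spectrogram, window: SOPWindow,
                            embedding: ObservedEmbedding) -> SVDDiagnostic:
    """Rank-2 SVD of the full SOP-window spectrogram as a structure check.

    In SOP recordings the full-window spectrogram is near rank-2: the leading
    temporal mode tracks total spectral power and the second tracks the
    transition coordinate.  Correlations are reported as absolute values;
    degenerate (zero-variance) pairings yield NaN with a warning.
    """
    cols = spec.column_slice(window.window_start, window.window_end)
    cols |= spec.times == window.window_end
    sub = spec.amplitudes[:, cols]
    times = spec.times[cols]
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    explained = s ** 2 / np.sum(s ** 2)

    def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn("zero-variance series in rank-2 diagnostic; "
                          "correlation undefined", stacklevel=3)
            return np.nan
        return float(abs(pearsonr(a, b)[0]))

    corr_power = _abs_corr(vt[0], sub.sum(axis=0))
    # align the (decimated, possibly column-skipped) embedding with columns
    col_idx = np.searchsorted(times, embedding.times)
    col_idx = np.clip(col_idx, 0, times.size - 1)
    corr_mu = _abs_corr(vt[1][col_idx], embedding.values)
    return SVDDiagnostic(singular_values=s, leading_temporal=vt[0],
                         second_temporal=vt[1], explained_variance=explained,
                         corr_power=corr_power, corr_embedding=corr_mu)


# ---------------------------------------------------------------------------
# input loading
# ---------------------------------------------------------------------------

def load_eeg(path: str, channel: str = "Oz", fs: Optional[float] = None
             ) -> Tuple[np.ndarray, float]:
    """Load a single EEG channel as (signal, sampling_rate).

    EDF files are read with MNE (channel selected by name, default ``Oz``);
    any other file is parsed as single-column delimited text, for which ``fs``
    must be given.
    """
    if str(path).lower().endswith(".edf"):
        import mne  # deferred: mne import is heavy

        raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
        data = raw.get_data(picks=[channel])[0]
        return np.asarray(data, dtype=float), float(raw.info["sfreq"])
    if fs is None:
        raise ValueError("fs is required for plain-text EEG input")
    data = np.loadtxt(path)
    if data.ndim != 1:
        data = data[:, 0]
    return np.asarray(data, dtype=float), float(fs)
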