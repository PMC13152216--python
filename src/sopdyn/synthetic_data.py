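"""Ground-truth synthetic subjects: embeddings, spectrograms, toy EEG.

Everything downstream of this module (window detection, SVD modes,
projection, inference, posterior predictive checks) is testable without any
external recording.  The generator draws latent paths from the bistable SDE,
observes them through the Gaussian noise model, and optionally renders a
spectrogram as the convex mixture of an alpha-peaked wake mode and a
low-frequency sleep mode — the same low-rank structure the embedding
extraction assumes, plus controllable multiplicative power noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .bistable_sde import LatentTrajectory, ModelParams, simulate_trajectory
from .spectral_embedding import (
    ObservedEmbedding,
    Spectrogram,
    SpectralModes,
    default_freq_grid,
)

__all__ = [
    "SyntheticSubject",
    "synthetic_modes",
    "synthetic_embedding",
    "synthetic_spectrogram",
    "synthetic_eeg",
    "recovery_grid",
    "FIXED_BETA_GRID",
    "FIXED_SIGMA_GRID",
    "TIME_VARYING_ALPHA_GRID",
    "TIME_VARYING_T0_GRID",
    "TIME_VARYING_SIGMA_GRID",
]

# study-condition grids for the two recovery scenarios
FIXED_BETA_GRID = tuple(np.round(np.arange(-0.8, 0.81, 0.2), 10))
FIXED_SIGMA_GRID = tuple(np.round(np.arange(0.2, 1.01, 0.1), 10))
TIME_VARYING_ALPHA_GRID = tuple(np.geomspace(0.05, 1.0, 10)) + (1.5,)
TIME_VARYING_T0_GRID = (40.0, 50.0, 60.0)
TIME_VARYING_SIGMA_GRID = FIXED_SIGMA_GRID

# Observation step of the simulated scenarios, model-time units.  The drift
# linearization rate at a stable well reaches 2(1 + |beta|) ~ 4 per model-time
# unit, so the one-step Euler transition density of the likelihood is only
# dynamically consistent for steps well below ~0.25; dt = 0.1 (rate x dt = 0.4)
# keeps the one-step density faithful while spanning the same 100-unit horizon
# as the drive-onset grid (t0 in {40, 50, 60}).
SIM_DT = 0.1
DEFAULT_N_OBS = 1001
DEFAULT_SIGMA_OBS = 1e-5


@dataclass(frozen=True)
class SyntheticSubject:
    """A synthetic subject: ground-truth parameters, latent path, observation."""

    true_params: ModelParams
    latent: LatentTrajectory
    embedding: ObservedEmbedding
    seed: int
    spectrogram: Optional[Spectrogram] = field(default=None, compare=False)
    modes: Optional[SpectralModes] = field(default=None, compare=False)


def synthetic_modes(freqs: Optional[np.ndarray] = None) -> SpectralModes:
    """Plausible wake/sleep spectral modes on a frequency grid.

    The wake mode is a unit-norm Gaussian bump centered at 10 Hz (sd 1 Hz,
    the alpha peak) over a small 1/f floor; the sleep mode is a 1/f-shaped
    profile with its mass concentrated in the 0.5-4 Hz delta band.  Both are
    non-negative and unit norm.  These emulate the leading SVD modes of real
    wake/sleep spectrogram segments; they are synthetic stand-ins, not
    measured spectra.
    """
    f = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    if f.min() > 0.5 or f.max() < 20.0:
        raise ValueError("frequency grid must cover [0.5, 20] Hz")
    wake = np.exp(-0.5 * ((f - 10.0) / 1.0) ** 2) + 0.05 / (f + 1.0)
    sleep = (f + 0.3) ** -1.5
    wake /= np.linalg.norm(wake)
    sleep /= np.linalg.norm(sleep)
    return SpectralModes(wake_mode=wake, sleep_mode=sleep, freqs=f)


def synthetic_embedding(params: ModelParams, n_obs: int = DEFAULT_N_OBS,
                        x0: float = 1.0, seed: int = 0,
                        substeps: int = 10) -> SyntheticSubject:
    """Simulate a latent path and observe it through Gaussian noise.

    The embedding is exactly ``latent state + N(0, sigma_obs^2)`` noise;
    with ``sigma_obs = 0`` it equals the latent states.  Fully reproducible
    from (params, x0, seed).
    """
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    latent = simulate_trajectory(params, x0=x0, n_steps=n_obs - 1,
                                 seed=seed, substeps=substeps)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 7]))
    noise = rng.standard_normal(n_obs) * params.sigma_obs
    values = latent.states + noise
    embedding = ObservedEmbedding(values=values, times=latent.times,
                                  step_seconds=params.dt)
    return SyntheticSubject(true_params=params, latent=latent,
                            embedding=embedding, seed=int(seed))


def synthetic_spectrogram(subject: SyntheticSubject,
                          modes: Optional[SpectralModes] = None,
                          power_noise: float = 0.0, seed: int = 0,
                          upsample: int = 10) -> Spectrogram:
    """Render a subject's latent path as a convex-mixture spectrogram.

    Latent states are linearly interpolated onto a grid ``upsample`` times
    finer (emulating the pre-decimation spectrogram resolution), mapped to
    mixture weights ``w = clip((x + 1)/2, 0, 1)``, and each column is
    ``w wake_mode + (1 - w) sleep_mode`` times multiplicative noise
    ``(1 + power_noise * N(0, 1))``, clipped non-negative.
    """
    modes = synthetic_modes() if modes is None else modes
    x = subject.latent.states
    t = subject.latent.times
    n_fine = x.size * upsample
    t_fine = np.linspace(t[0], t[-1], n_fine)
    x_fine = np.interp(t_fine, t, x)
    w = np.clip((x_fine + 1.0) / 2.0, 0.0, 1.0)
    amp = np.outer(modes.wake_mode, w) + np.outer(modes.sleep_mode, 1.0 - w)
    if power_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 11]))
        amp = amp * (1.0 + power_noise * rng.standard_normal(amp.shape))
        amp = np.clip(amp, 0.0, None)
    return Spectrogram(freqs=modes.freqs, times=t_fine, amplitudes=amp)


def synthetic_eeg(weights: np.ndarray, fs: float = 100.0, seed: int = 0,
                  noise_sd: float = 0.05) -> np.ndarray:
    """Toy time-domain EEG: mixture-weighted 10 Hz and 2 Hz carriers.

    ``weights`` in [0, 1] modulate an alpha-band (10 Hz) sinusoid against a
    delta-band (2 Hz) sinusoid, sample by sample, plus white noise.
    Sufficient for exercising filtering, resampling and band-ratio logic;
    not claimed to be physiological.
    """
    w = np.clip(np.asarray(weights, dtype=float), 0.0, 1.0)
    t = np.arange(w.size) / fs
    rng = np.random.default_rng(seed)
    sig = (w * np.sin(2 * np.pi * 10.0 * t)
           + (1.0 - w) * 2.0 * np.sin(2 * np.pi * 2.0 * t)
           + noise_sd * rng.standard_normal(w.size))
    return sig


def _cell_seed(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Independent, reproducible per-cell seed stream."""
    return np.random.SeedSequence([int(master_seed) % (2 ** 31), *[int(i) for i in indices]])


def recovery_grid(scenario: str, n_per_cell: int = 30, seed: int = 0,
                  n_obs: int = DEFAULT_N_OBS,
                  sigma_obs: float = DEFAULT_SIGMA_OBS,
                  alpha_values: Optional[Sequence[float]] = None,
                  t0_values: Optional[Sequence[float]] = None,
                  sigma_values: Optional[Sequence[float]] = None,
                  beta_values: Optional[Sequence[float]] = None,
                  ) -> List[SyntheticSubject]:
    """Synthetic subjects over a parameter-recovery study grid.

    ``scenario="fixed"``: stationary landscape, the unstable point held at
    each beta in [-0.8 : 0.2 : 0.8] crossed with sigma in [0.2 : 0.1 : 1.0],
    initial state 0.  ``scenario="time_varying"``: drive steepness over 10
    log-spaced values in [0.05, 1] plus 1.5, onset in {40, 50, 60}, sigma in
    [0.2 : 0.1 : 1.0], initial state 1.  Pass explicit value sequences to
    restrict any axis (reduced-scale studies).  Per-cell seeds derive from
    the master seed and the cell indices, so cells are independent and any
    subset is reproducible in isolation.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    subjects: List[SyntheticSubject] = []
    if scenario == "fixed":
        betas = FIXED_BETA_GRID if beta_values is None else tuple(beta_values)
        sigmas = FIXED_SIGMA_GRID if sigma_values is None else tuple(sigma_values)
        for i_b, beta in enumerate(betas):
            for i_s, sig in enumerate(sigmas):
                for rep in range(n_per_cell):
                    params = ModelParams(alpha=0.0, t0=0.0, sigma=float(sig),
                                         sigma_obs=sigma_obs, dt=SIM_DT,
                                         beta_const=float(beta))
                    sub_seed = int(_cell_seed(seed, 1, i_b, i_s, rep)
                                   .generate_state(1)[0] % (2 ** 31))
                    subjects.append(synthetic_embedding(params, n_obs=n_obs,
                                                        x0=0.0, seed=sub_seed))
    elif scenario == "time_varying":
        alphas = TIME_VARYING_ALPHA_GRID if alpha_values is None else tuple(alpha_values)
        t0s = TIME_VARYING_T0_GRID if t0_values is None else tuple(t0_values)
        sigmas = TIME_VARYING_SIGMA_GRID if sigma_values is None else tuple(sigma_values)
        for i_a, alpha in enumerate(alphas):
            for i_t, t0 in enumerate(t0s):
                for i_s, sig in enumerate(sigmas):
                    for rep in range(n_per_cell):
                        params = ModelParams(alpha=float(alpha), t0=float(t0),
                                             sigma=float(sig), sigma_obs=sigma_obs,
                                             dt=SIM_DT)
                        sub_seed = int(_cell_seed(seed, 2, i_a, i_t, i_s, rep)
                                       .generate_state(1)[0] % (2 ** 31))
                        subjects.append(synthetic_embedding(params, n_obs=n_obs,
                                                            x0=1.0, seed=sub_seed))
    else:
        raise ValueError("scenario must be 'fixed' or 'time_varying'")
    return subjects
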