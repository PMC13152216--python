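"""Shared fixtures: small synthetic subjects and one pre-fitted posterior."""

from dataclasses import replace

import numpy as np
import pytest

import sopdyn as sd


@pytest.fixture(scope="session")
def sim_params():
    """Moderate time-varying scenario on the simulated observation grid."""
    return sd.ModelParams(alpha=0.2, t0=50.0, sigma=0.5, sigma_obs=1e-5, dt=0.1)


@pytest.fixture(scope="session")
def subject(sim_params):
    """One full-horizon synthetic subject (100 model-time units)."""
    return sd.synthetic_embedding(sim_params, n_obs=1001, x0=1.0, seed=42)


@pytest.fixture(scope="session")
def small_subject():
    """Short-horizon subject for fast inference tests (20 model-time units)."""
    params = sd.ModelParams(alpha=0.5, t0=10.0, sigma=0.5, sigma_obs=1e-5, dt=0.1)
    return sd.synthetic_embedding(params, n_obs=201, x0=1.0, seed=7)


@pytest.fixture(scope="session")
def small_priors(small_subject):
    """Simulated-context priors recentered on the short horizon."""
    return replace(sd.default_priors("simulated"), t0_mean=10.0, t0_sd=5.0)


@pytest.fixture(scope="session")
def quick_draws(small_subject, small_priors):
    """A fast posterior fit shared by the evaluation tests."""
    cfg = sd.SamplerConfig(chains=2, warmup=300, dt=0.1)
    return sd.sample_posterior(small_subject.embedding, small_priors,
                               n_draws=400, seed=11, config=cfg)


@pytest.fixture(scope="session")
def synthetic_modes():
    return sd.synthetic_modes()


def plateau_spectrogram(modes, n=1001, t_lo=10.0, t_hi=90.0):
    """Two-mode mixture spectrogram with pure-wake and pure-sleep plateaus.

    Returns (spectrogram, SOP window, true mixture weights); the plateaus make
    the wake/sleep anchor segments exactly pure, so the affine projection
    recovers the weights without approximation.
    """
    t = np.linspace(0.0, 100.0, n)
    w = np.clip((np.tanh(0.2 * (50.0 - t)) + 1) / 2, 0.0, 1.0)
    w[t < t_lo] = 1.0
    w[t > t_hi] = 0.0
    amp = np.outer(modes.wake_mode, w) + np.outer(modes.sleep_mode, 1 - w)
    spec = sd.Spectrogram(freqs=modes.freqs, times=t, amplitudes=amp)
    win = sd.SOPWindow(t_start=40.0, t_end=60.0, window_start=0.0,
                       window_end=100.0, segment_seconds=t_lo)
    return spec, win, w
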