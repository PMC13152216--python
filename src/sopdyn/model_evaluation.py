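"""Posterior predictive checking and switching statistics.

Given posterior draws for one embedding, this module forward-simulates
predictive trajectories (one per draw, under the same one-step Euler
discretization that defines the likelihood), scores each against the data
with a pooled Kullback-Leibler divergence and RMSE, selects representative
trajectories (minimum-KL, minimum-RMSE, joint-MAP), decomposes the joint log
likelihood into per-timepoint observation and transition terms, and counts
committed state switches with a hysteresis zero-crossing rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde

from .bayes_inference import PosteriorDraws

__all__ = [
    "SimulatedTrajectories",
    "PPCResult",
    "LikelihoodDecomposition",
    "SwitchStats",
    "posterior_predictive",
    "kl_pooled",
    "rmse",
    "select_representatives",
    "likelihood_timecourse",
    "count_switches",
]


@dataclass(frozen=True)
class SimulatedTrajectories:
    """Forward-simulated predictive trajectories with their generating draws."""

    states: np.ndarray        # (n_traj, T)
    draw_indices: np.ndarray  # (n_traj,) index into the PosteriorDraws
    seed: int

    def __len__(self) -> int:
        return self.states.shape[0]


@dataclass(frozen=True)
class PPCResult:
    """Posterior predictive check summary.

    Per-trajectory KL divergences and RMSEs, the three representative
    trajectories (argmin-KL, argmin-RMSE, joint-MAP) with their indices, the
    pooled-distribution KDE modes of both metrics, and per-timepoint 10%/90%
    predictive bands.
    """

    kl_values: np.ndarray
    rmse_values: np.ndarray
    min_kl_index: int
    min_rmse_index: int
    joint_map_index: int
    min_kl_traj: np.ndarray
    min_rmse_traj: np.ndarray
    joint_map_traj: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    kl_mode: float = np.nan
    rmse_mode: float = np.nan

    def __post_init__(self) -> None:
        if np.any(self.kl_values < 0) or np.any(self.rmse_values < 0):
            raise ValueError("KL and RMSE values must be non-negative")
        if np.any(self.band_lo > self.band_hi):
            raise ValueError("band_lo must not exceed band_hi")


@dataclass(frozen=True)
class LikelihoodDecomposition:
    """Per-timepoint mean observation/transition log-likelihood series.

    Both series have one value per transition step (aligned to observations
    1..N); ``obs_mode`` and ``trans_mode`` are the modes of Gaussian kernel
    density estimates of the pooled series.
    """

    obs_loglik_t: np.ndarray
    trans_loglik_t: np.ndarray
    obs_mode: float
    trans_mode: float


@dataclass(frozen=True)
class SwitchStats:
    """Committed wake/sleep switch count of a state or embedding series."""

    n_switches: int
    crossing_indices: np.ndarray
    settings: dict

    def __post_init__(self) -> None:
        ci = np.asarray(self.crossing_indices, dtype=int)
        if ci.size != self.n_switches:
            raise ValueError("n_switches must equal len(crossing_indices)")
        if ci.size > 1 and np.any(np.diff(ci) <= 0):
            raise ValueError("crossing_indices must be strictly increasing")
        object.__setattr__(self, "crossing_indices", ci)


# ---------------------------------------------------------------------------
# posterior predictive simulation
# ---------------------------------------------------------------------------

def posterior_predictive(draws: PosteriorDraws, obs, n_traj: Optional[int] = None,
                         seed: int = 0) -> SimulatedTrajectories:
    """Forward-simulate one trajectory per posterior draw.

    Each trajectory starts at the first observed embedding value and evolves
    by the one-step Euler scheme of the likelihood: ``x_{i+1} = x_i +
    eps f(x_i; beta_i) dt + sigma sqrt(eps dt) xi`` with
    ``beta_i = tanh(alpha eps (i dt - t0))`` from that draw's parameters.
    When ``n_traj`` is below the number of draws the first ``n_traj`` draws
    are used; above, draws are resampled with replacement.
    """
    mu = obs.values if hasattr(obs, "values") else np.asarray(obs, dtype=float)
    T = mu.size
    n_draws = draws.n_draws
    n = n_draws if n_traj is None else int(n_traj)
    rng = np.random.default_rng(seed)
    if n <= n_draws:
        idx = np.arange(n)
    else:
        idx = rng.integers(0, n_draws, n)

    p = draws.params
    sigma = p["sigma"][idx]
    dt = draws.dt
    if draws.model == "stationary":
        eps = np.ones(n)
        beta_grid = np.broadcast_to(p["beta"][idx], (T - 1, n)).T
    else:
        eps = p["epsilon"][idx]
        alpha, t0 = p["alpha"][idx], p["t0"][idx]
        ti = np.arange(T - 1) * dt
        beta_grid = np.tanh(alpha[:, None] * eps[:, None] * (ti[None, :] - t0[:, None]))

    noise_scale = sigma * np.sqrt(eps * dt)
    states = np.empty((n, T))
    states[:, 0] = mu[0]
    x = np.full(n, mu[0])
    for i in range(T - 1):
        b = beta_grid[:, i]
        f = -(x + 1.0) * (x - b) * (x - 1.0)
        x = x + eps * f * dt + noise_scale * rng.standard_normal(n)
        states[:, i + 1] = x
    return SimulatedTrajectories(states=states, draw_indices=idx, seed=int(seed))


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def kl_pooled(sim: np.ndarray, obs: np.ndarray, bins: int = 50,
              eps: float = 1e-10) -> float:
    """KL(observed || simulated) of the time-pooled value distributions.

    Both series are histogrammed on a shared grid spanning their joint range;
    ``eps`` regularizes empty bins before normalization.
    """
    sim = np.asarray(sim, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if sim.size == 0 or obs.size == 0:
        raise ValueError("series must be non-empty")
    lo = min(sim.min(), obs.min())
    hi = max(sim.max(), obs.max())
    if lo == hi:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(obs, bins=edges)
    q, _ = np.histogram(sim, bins=edges)
    p = p.astype(float) / p.sum() + eps
    q = q.astype(float) / q.sum() + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def rmse(sim: np.ndarray, obs: np.ndarray) -> float:
    """Root mean square pointwise difference between two equal-length series."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("series length mismatch")
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def _kde_mode(values: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a regular grid."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.std(values) == 0:
        return float(values[0]) if values.size else np.nan
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    return float(grid[np.argmax(kde(grid))])


def select_representatives(trajs: SimulatedTrajectories, draws: PosteriorDraws,
                           obs, bins: int = 50) -> PPCResult:
    """Score all predictive trajectories and select the representatives.

    Computes KL and RMSE per trajectory; selects the argmin-KL and argmin-RMSE
    trajectories (ties: lowest index) and the trajectory whose generating draw
    maximizes the joint log density; reports pooled KDE modes of both metrics
    and the per-timepoint 10%/90% predictive band.
    """
    mu = obs.values if hasattr(obs, "values") else np.asarray(obs, dtype=float)
    states = trajs.states
    if states.shape[0] == 0:
        raise ValueError("empty trajectory set")
    kl_values = np.array([kl_pooled(s, mu, bins=bins) for s in states])
    rmse_values = np.array([rmse(s, mu) for s in states])
    i_kl = int(np.argmin(kl_values))
    i_rmse = int(np.argmin(rmse_values))
    lj = draws.log_joint_values[trajs.draw_indices]
    i_map = int(np.argmax(lj))
    # quantile conventions chosen so two trajectories give the min/max envelope
    band_lo = np.quantile(states, 0.1, axis=0, method="lower")
    band_hi = np.quantile(states, 0.9, axis=0, method="higher")
    return PPCResult(
        kl_values=kl_values, rmse_values=rmse_values,
        min_kl_index=i_kl, min_rmse_index=i_rmse, joint_map_index=i_map,
        min_kl_traj=states[i_kl], min_rmse_traj=states[i_rmse],
        joint_map_traj=states[i_map],
        band_lo=band_lo, band_hi=band_hi,
        kl_mode=_kde_mode(kl_values), rmse_mode=_kde_mode(rmse_values),
    )


# ---------------------------------------------------------------------------
# likelihood decomposition
# ---------------------------------------------------------------------------

def likelihood_timecourse(draws: PosteriorDraws, obs) -> LikelihoodDecomposition:
    """Per-timepoint observation/transition log-likelihood, averaged over draws.

    For each draw the one-step joint density splits into an observation term
    ``log N(mu_{t+1} | x_{t+1}, sigma_obs)`` and a transition term
    ``log N(x_{t+1} | m_t, v)``; both are evaluated on that draw's sampled
    latent path and averaged across draws at each timepoint.  The modes of
    Gaussian KDEs of the two pooled series summarize goodness of fit.
    """
    mu = obs.values if hasattr(obs, "values") else np.asarray(obs, dtype=float)
    x = draws.latent_paths           # (S, T)
    if x.ndim != 2 or x.shape[1] != mu.size:
        raise ValueError("latent paths do not match the embedding length")
    S, T = x.shape
    p = draws.params
    sobs = p["sigma_obs"][:, None]
    sigma = p["sigma"][:, None]
    dt = draws.dt
    if draws.model == "stationary":
        eps = np.ones((S, 1))
        beta = np.broadcast_to(p["beta"][:, None], (S, T - 1))
    else:
        eps = p["epsilon"][:, None]
        ti = np.arange(T - 1) * dt
        beta = np.tanh(p["alpha"][:, None] * eps * (ti[None, :] - p["t0"][:, None]))
    xc, xn = x[:, :-1], x[:, 1:]
    f = -(xc + 1.0) * (xc - beta) * (xc - 1.0)
    m = xc + eps * f * dt
    v = sigma ** 2 * eps * dt
    obs_ll = (-0.5 * np.log(2.0 * np.pi * sobs ** 2)
              - 0.5 * ((mu[None, 1:] - xn) / sobs) ** 2)
    trans_ll = -0.5 * np.log(2.0 * np.pi * v) - 0.5 * (xn - m) ** 2 / v
    obs_series = obs_ll.mean(axis=0)
    trans_series = trans_ll.mean(axis=0)
    return LikelihoodDecomposition(
        obs_loglik_t=obs_series, trans_loglik_t=trans_series,
        obs_mode=_kde_mode(obs_series), trans_mode=_kde_mode(trans_series),
    )


# ---------------------------------------------------------------------------
# switch counting
# ---------------------------------------------------------------------------

def count_switches(series: np.ndarray, smooth_window: int = 1,
                   hysteresis: float = 0.1, commit: int = 50) -> SwitchStats:
    """Count committed wake/sleep switches with a robust zero-crossing rule.

    The series is moving-average smoothed (``smooth_window`` samples), a
    binary state is assigned by sign with a hysteresis dead band (values in
    ``[-hysteresis, +hysteresis]`` keep the previous state), and a switch is
    counted only when the new state persists for at least ``commit``
    consecutive samples; shorter excursions are ignored.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= commit:
        raise ValueError("series must be longer than the commitment length")
    if smooth_window > 1:
        kernel = np.ones(int(smooth_window)) / int(smooth_window)
        x = np.convolve(x, kernel, mode="same")

    # hysteresis state assignment (in-band samples keep the previous state)
    state = np.zeros(x.size, dtype=int)
    s = 0
    for i, v in enumerate(x):
        if v > hysteresis:
            s = 1
        elif v < -hysteresis:
            s = -1
        state[i] = s

    # a state counts only once held for `commit` consecutive samples; the
    # first committed state is the baseline, every later committed state
    # change is a switch at the run start
    committed = 0
    crossings = []
    n = x.size
    i = 0
    while i < n:
        s = int(state[i])
        if s != 0 and s != committed:
            j = i
            while j < n and state[j] == s:
                j += 1
            if j - i >= commit:
                if committed != 0:
                    crossings.append(i)
                committed = s
            i = j
        else:
            i += 1
    settings = {"smooth_window": int(smooth_window), "hysteresis": float(hysteresis),
                "commit": int(commit)}
    return SwitchStats(n_switches=len(crossings),
                       crossing_indices=np.asarray(crossings, dtype=int),
                       settings=settings)
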