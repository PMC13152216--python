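"""Stochastic bistable dynamics of the wake-to-sleep transition.

The latent sleep-onset state ``x(t)`` moves in a cubic double-well landscape
whose barrier is slowly tilted by a sleep drive ``beta(t)``:

    dx = -(x + 1) (x - beta(t)) (x - 1) dt + sigma dW,
    beta(t) = tanh(alpha (t - t0)).

The two stable equilibria sit at ``x = +1`` (wake) and ``x = -1`` (sleep) for
every drive value strictly inside (-1, 1); the unstable equilibrium sits at
``beta``.  As the drive saturates toward +1 the wake basin flattens and
noise-driven transitions to sleep become increasingly likely, producing the
intermittent "flickering" seen in sleep-onset EEG.

This module provides the drift, the drive, and a seeded Euler-Maruyama
forward simulator.  Time is *model time*; the mapping to observation samples
(via the time-scale factor ``epsilon``) is handled by the inference module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "ModelParams",
    "LatentTrajectory",
    "IntegrationError",
    "drift",
    "beta_of_t",
    "simulate_trajectory",
]


class IntegrationError(RuntimeError):
    """Raised when the Euler-Maruyama integration produces a non-finite state."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the bistable sleep-onset model.

    Parameters
    ----------
    alpha : float
        Steepness of the sleep drive, per model-time unit.  ``alpha >= 0``
        (the drive is non-decreasing toward sleep).
    t0 : float
        Drive onset time (the inflection of the tanh), model-time units.
    sigma : float
        Diffusion strength, state units per sqrt(model-time).  ``sigma > 0``.
    epsilon : float
        Time-scale factor mapping observation index to model time
        (``t* = epsilon t``).  ``epsilon > 0``.
    sigma_obs : float
        Observation-noise standard deviation, state units.  ``>= 0``.
    dt : float
        Integration/observation step in model-time units (default 1.0).
    beta_const : float, optional
        When set, the drive is held fixed at this value (stationary-landscape
        scenario); ``alpha`` and ``t0`` are then ignored by the simulator.
    """

    alpha: float
    t0: float
    sigma: float
    epsilon: float = 1.0
    sigma_obs: float = 0.0
    dt: float = 1.0
    beta_const: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("alpha", "t0", "sigma", "epsilon", "sigma_obs", "dt"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0 (drive is non-decreasing)")
        if self.beta_const is not None and not np.isfinite(self.beta_const):
            raise ValueError("beta_const must be finite")

    def drive_at(self, t: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Drive value beta(t) at model time ``t`` (honours ``beta_const``)."""
        if self.beta_const is not None:
            return np.broadcast_to(self.beta_const, np.shape(t)).copy() if np.ndim(t) else self.beta_const
        return beta_of_t(t, self.alpha, self.t0)


@dataclass(frozen=True)
class LatentTrajectory:
    """A simulated latent state path with its drive path.

    ``times`` is the uniform model-time grid, ``states`` the state values,
    ``drive`` the drive beta(t) evaluated on the same grid, and ``seed`` the
    integer that generated the Wiener increments (same params, x0 and seed
    reproduce the path bit-for-bit).
    """

    times: np.ndarray
    states: np.ndarray
    drive: np.ndarray
    seed: int
    params: Optional[ModelParams] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t, x, b = (np.asarray(a, dtype=float) for a in (self.times, self.states, self.drive))
        if not (t.shape == x.shape == b.shape) or t.ndim != 1:
            raise ValueError("times, states and drive must be 1-D arrays of equal length")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing with uniform spacing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)
        object.__setattr__(self, "drive", b)

    def __len__(self) -> int:
        return self.times.size

    def to_text(self, path_or_buf) -> None:
        """Write the trajectory as two-column delimited text (time, state)."""
        np.savetxt(path_or_buf, np.column_stack([self.times, self.states]),
                   delimiter="\t", header="time\tstate", comments="")

    @classmethod
    def from_text(cls, path_or_buf, seed: int = -1) -> "LatentTrajectory":
        data = np.loadtxt(path_or_buf, delimiter="\t", skiprows=1)
        t, x = data[:, 0], data[:, 1]
        return cls(times=t, states=x, drive=np.full_like(x, np.nan), seed=seed)


def drift(x, beta):
    """Deterministic force -(x + 1)(x - beta)(x - 1) of the cubic landscape.

    Zero exactly at ``x in {-1, beta, +1}``; the outer roots are stable
    (negative linearized slope) and ``beta`` is unstable for
    ``beta`` strictly inside (-1, 1).  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    beta_arr = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(beta_arr)):
        raise ValueError("drift requires finite inputs")
    if np.any(beta_arr < -1.0) or np.any(beta_arr > 1.0):
        raise ValueError("beta must lie in [-1, 1]")
    out = -(x + 1.0) * (x - beta_arr) * (x - 1.0)
    return out if out.ndim else float(out)


def beta_of_t(t, alpha, t0):
    """Sleep drive beta(t) = tanh(alpha (t - t0)).

    Strictly increasing in ``t`` for ``alpha > 0``, saturating toward +/-1;
    identically zero for ``alpha = 0``.
    """
    out = np.tanh(alpha * (np.asarray(t, dtype=float) - t0))
    return out if out.ndim else float(out)


def simulate_trajectory(
    params: ModelParams,
    x0: float,
    n_steps: int,
    seed: int,
    substeps: int = 10,
    record_substeps: bool = False,
) -> LatentTrajectory:
    """Euler-Maruyama forward simulation of the bistable SDE in model time.

    Integrates with internal step ``dt / substeps`` and Gaussian increments of
    variance ``sigma^2 dt / substeps``; records states on the observation grid
    (``n_steps + 1`` samples spaced ``dt``), or on the fine grid when
    ``record_substeps`` is set (used by switch statistics, where the committed
    dwell rule needs finer temporal resolution than the observation grid).

    Deterministic given ``seed``: the Wiener increments come from
    ``numpy.random.default_rng(seed)``.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite; the message names the fine-step index.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if not np.isfinite(x0):
        raise ValueError("x0 must be finite")

    h = params.dt / substeps
    n_fine = n_steps * substeps
    t_fine = np.arange(n_fine + 1) * h
    beta_fine = np.asarray(params.drive_at(t_fine), dtype=float)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_fine) * (params.sigma * np.sqrt(h))

    x_fine = np.empty(n_fine + 1)
    x_fine[0] = x0
    x = float(x0)
    for k in range(n_fine):
        x = x + drift(x, beta_fine[k]) * h + noise[k]
        if not np.isfinite(x):
            raise IntegrationError(
                f"state became non-finite at fine step {k + 1} "
                f"(model time {t_fine[k + 1]:.3f}); check sigma/dt"
            )
        x_fine[k + 1] = x

    if record_substeps:
        times, states, drive_rec = t_fine, x_fine, beta_fine
    else:
        idx = np.arange(0, n_fine + 1, substeps)
        times, states, drive_rec = t_fine[idx], x_fine[idx], beta_fine[idx]
    return LatentTrajectory(times=times, states=states, drive=drive_rec,
                            seed=seed, params=params)
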