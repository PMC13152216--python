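"""Single-trajectory Bayesian inference for the bistable sleep-onset model.

The observed transition coordinate ``mu_0:N`` is modelled as a latent path of
the cubic SDE corrupted by Gaussian observation noise,

    mu_i = x_i + eta_i,              eta_i ~ N(0, sigma_obs^2),
    x_{i+1} | x_i ~ N(m_i, v),       m_i = x_i + eps f(x_i; beta_i) dt,
                                     v   = sigma^2 eps dt,
    beta_i = tanh(alpha eps (t_i - t0)),   t_i = i dt,

where ``f`` is the cubic drift and ``eps`` is a time-scale factor aligning
the model clock with the (unknown) effective clock of the recording.  The
joint log posterior over parameters and the latent path is the prior plus the
sum of the observation and one-step Euler transition log densities.

Sampling targets the joint (theta, x_0:N) with Hamiltonian Monte Carlo using
analytic gradients: constrained parameters are mapped to unconstrained scales
(log for the half-normal-supported alpha and sigma, logit for the
uniform-supported eps and sigma_obs) with Jacobian corrections, and the path
is preconditioned as ``x = mu + s_x u`` with ``s_x`` the observation-noise
scale, so that all coordinates are O(1) and a diagonal metric suffices.
Step size is tuned by dual averaging and the metric by windowed variance
estimation during warmup; split R-hat and effective sample size are reported
per parameter (via arviz).

A stationary-landscape variant (fixed unstable-point location ``beta``,
parameters ``(beta, sigma)``, eps = 1) is available through
``SamplerConfig(model="stationary")``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm as _norm

from .bistable_sde import ModelParams

__all__ = [
    "PriorSpec",
    "OneStepDensity",
    "PosteriorDraws",
    "SamplerConfig",
    "ConvergenceWarning",
    "default_priors",
    "observation_loglik",
    "transition_loglik",
    "log_joint",
    "sample_posterior",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when split R-hat exceeds 1.05 for any parameter."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Prior specification for the model parameters.

    ``epsilon`` and ``sigma_obs`` are each either a fixed float (simulated
    context: the model clock is the simulation clock and the latent path is
    pinned to the observations) or a (lo, hi) uniform-bound pair
    (experimental context).  ``beta_mean``/``beta_sd`` parameterize the
    normal prior on the fixed unstable-point location used by the
    stationary-landscape variant.
    """

    context: str
    alpha_scale: float = 1.0
    t0_mean: float = 50.0
    t0_sd: float = 10.0
    sigma_scale: float = 2.0
    epsilon: Union[float, Tuple[float, float]] = 1.0
    sigma_obs: Union[float, Tuple[float, float]] = 1e-5
    beta_mean: float = 0.0
    beta_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_scale <= 0 or self.sigma_scale <= 0 or self.t0_sd <= 0 \
                or self.beta_sd <= 0:
            raise ValueError("prior scales and sds must be strictly positive")
        if self.samples_epsilon:
            lo, hi = self.epsilon
            if not 0 < lo < hi:
                raise ValueError("epsilon bounds must satisfy 0 < lo < hi")
        elif self.epsilon <= 0:
            raise ValueError("fixed epsilon must be > 0")
        if self.samples_sigma_obs:
            olo, ohi = self.sigma_obs
            if not 0 < olo < ohi:
                raise ValueError("sigma_obs bounds must satisfy 0 < lo < hi")
        elif self.sigma_obs <= 0:
            raise ValueError("fixed sigma_obs must be > 0")

    @property
    def samples_epsilon(self) -> bool:
        return isinstance(self.epsilon, (tuple, list))

    @property
    def samples_sigma_obs(self) -> bool:
        return isinstance(self.sigma_obs, (tuple, list))

    def sigma_obs_value(self) -> float:
        """Fixed value, or the bound midpoint when sigma_obs is sampled."""
        if self.samples_sigma_obs:
            return 0.5 * (self.sigma_obs[0] + self.sigma_obs[1])
        return float(self.sigma_obs)

    def log_prior(self, params: ModelParams) -> float:
        """Joint log prior density of a parameter point; -inf outside support."""
        lp = 0.0
        if params.beta_const is not None:  # stationary-landscape variant
            lp += _norm.logpdf(params.beta_const, self.beta_mean, self.beta_sd)
        else:
            if params.alpha < 0:
                return -np.inf
            lp += _halfnormal_logpdf(params.alpha, self.alpha_scale)
            lp += _norm.logpdf(params.t0, self.t0_mean, self.t0_sd)
            if self.samples_epsilon:
                lo, hi = self.epsilon
                if not lo <= params.epsilon <= hi:
                    return -np.inf
                lp += -math.log(hi - lo)
        if params.sigma <= 0:
            return -np.inf
        lp += _halfnormal_logpdf(params.sigma, self.sigma_scale)
        if self.samples_sigma_obs:
            olo, ohi = self.sigma_obs
            if not olo <= params.sigma_obs <= ohi:
                return -np.inf
            lp += -math.log(ohi - olo)
        return float(lp)

    def sample(self, n: int, seed: int = 0) -> Dict[str, np.ndarray]:
        """Independent prior draws per parameter (for prior predictive checks)."""
        rng = np.random.default_rng(seed)
        out = {
            "alpha": np.abs(rng.normal(0.0, self.alpha_scale, n)),
            "t0": rng.normal(self.t0_mean, self.t0_sd, n),
            "sigma": np.abs(rng.normal(0.0, self.sigma_scale, n)),
            "beta": rng.normal(self.beta_mean, self.beta_sd, n),
        }
        if self.samples_epsilon:
            out["epsilon"] = rng.uniform(*self.epsilon, n)
        else:
            out["epsilon"] = np.full(n, float(self.epsilon))
        if self.samples_sigma_obs:
            out["sigma_obs"] = rng.uniform(*self.sigma_obs, n)
        else:
            out["sigma_obs"] = np.full(n, float(self.sigma_obs))
        return out


def _halfnormal_logpdf(v: float, scale: float) -> float:
    if v < 0:
        return -np.inf
    return math.log(2.0) - 0.5 * _LOG_2PI - math.log(scale) - 0.5 * (v / scale) ** 2


def default_priors(context: str, n_obs: Optional[int] = None) -> PriorSpec:
    """Default priors for the simulated and experimental contexts.

    Simulated: alpha ~ HalfNormal(1), t0 ~ Normal(50, 10),
    sigma ~ HalfNormal(2), with the time-scale factor fixed at eps = 1 and
    sigma_obs fixed at 1e-5 (the simulation clock is the model clock and the
    sampled path is forced to track the observed trajectory).
    Experimental: t0 ~ Normal(N/2, N/4) with N the embedding length,
    eps ~ Uniform(0.1, 5) and sigma_obs ~ Uniform(0.1, 0.4); the rest
    identical.
    """
    if context == "simulated":
        return PriorSpec(context=context, epsilon=1.0)
    if context == "experimental":
        if n_obs is None or n_obs < 30:
            raise ValueError("experimental context requires n_obs >= 30")
        return PriorSpec(context=context, t0_mean=n_obs / 2.0, t0_sd=n_obs / 4.0,
                         epsilon=(0.1, 5.0), sigma_obs=(0.1, 0.4))
    raise ValueError(f"unknown context {context!r}: use 'simulated' or 'experimental'")


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneStepDensity:
    """Conditional mean and variance of the one-step Euler transition."""

    m: float
    v: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("one-step variance must be > 0")


def observation_loglik(mu: float, x: float, sigma_obs: float) -> float:
    """Gaussian log density of the observation given the latent state."""
    if sigma_obs <= 0:
        raise ValueError("sigma_obs must be > 0")
    z = (mu - x) / sigma_obs
    return -0.5 * _LOG_2PI - math.log(sigma_obs) - 0.5 * z * z


def _drive_at_index(params: ModelParams, obs_index) -> Union[float, np.ndarray]:
    """beta_i = tanh(alpha eps (t_i - t0)) on the observation-index clock."""
    if params.beta_const is not None:
        return params.beta_const
    t_i = np.asarray(obs_index, dtype=float) * params.dt
    out = np.tanh(params.alpha * params.epsilon * (t_i - params.t0))
    return out if out.ndim else float(out)


def transition_loglik(x_next: float, x_curr: float, params: ModelParams,
                      obs_index: int) -> Tuple[float, OneStepDensity]:
    """One-step Euler transition log density and its (mean, variance) pair."""
    beta_i = _drive_at_index(params, obs_index)
    f = -(x_curr + 1.0) * (x_curr - beta_i) * (x_curr - 1.0)
    m = x_curr + params.epsilon * f * params.dt
    v = params.sigma ** 2 * params.epsilon * params.dt
    dens = OneStepDensity(m=float(m), v=float(v))
    z = (x_next - m) / math.sqrt(v)
    ld = -0.5 * _LOG_2PI - 0.5 * math.log(v) - 0.5 * z * z
    return float(ld), dens


def log_joint(params: ModelParams, x_path: np.ndarray, mu_path: np.ndarray,
              priors: PriorSpec) -> float:
    """Joint log density of parameters and latent path given the embedding.

    Equals ``log_prior + sum_i obs_loglik(mu_i, x_i) +
    sum_i trans_loglik(x_{i+1}, x_i)``; -inf outside the prior support.
    """
    x = np.asarray(x_path, dtype=float)
    mu = np.asarray(mu_path, dtype=float)
    if x.shape != mu.shape or x.ndim != 1:
        raise ValueError("x_path and mu_path must be 1-D arrays of equal length")
    if x.size < 1:
        raise ValueError("paths must contain at least one sample")
    lp = priors.log_prior(params)
    if not np.isfinite(lp):
        return -np.inf
    return lp + _loglik_terms(params, x, mu).sum()


def _loglik_terms(params: ModelParams, x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Vector of [all observation terms..., all transition terms...]."""
    sobs = params.sigma_obs
    if sobs <= 0:
        raise ValueError("sigma_obs must be > 0 for the observation model")
    obs = -0.5 * _LOG_2PI - math.log(sobs) - 0.5 * ((mu - x) / sobs) ** 2
    if x.size == 1:
        return obs
    idx = np.arange(x.size - 1)
    beta = np.broadcast_to(_drive_at_index(params, idx), idx.shape)
    xc, xn = x[:-1], x[1:]
    f = -(xc + 1.0) * (xc - beta) * (xc - 1.0)
    m = xc + params.epsilon * f * params.dt
    v = params.sigma ** 2 * params.epsilon * params.dt
    trans = -0.5 * _LOG_2PI - 0.5 * math.log(v) - 0.5 * (xn - m) ** 2 / v
    return np.concatenate([obs, trans])


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Joint posterior samples of parameters and latent paths.

    ``params`` maps parameter names to arrays of length ``n_draws``;
    ``latent_paths`` has shape ``(n_draws, N + 1)``.  ``log_joint_values``
    holds the (Jacobian-free) joint log density of each draw, used for
    joint-MAP trajectory selection.  ``diagnostics`` maps parameter names to
    split R-hat and bulk effective sample size.
    """

    params: Dict[str, np.ndarray]
    latent_paths: np.ndarray
    n_draws: int
    seed: int
    diagnostics: Dict[str, Dict[str, float]]
    log_joint_values: np.ndarray
    priors: PriorSpec
    model: str
    dt: float
    chains: int
    accept_rate: float

    def __post_init__(self) -> None:
        for name, arr in self.params.items():
            if arr.shape != (self.n_draws,):
                raise ValueError(f"parameter {name} has wrong draw count")
        if self.latent_paths.shape[0] != self.n_draws:
            raise ValueError("latent_paths draw count mismatch")

    def param_names(self):
        return list(self.params)

    def mean(self, name: str) -> float:
        return float(self.params[name].mean())

    def quantile(self, name: str, q) -> np.ndarray:
        return np.quantile(self.params[name], q)

    def model_params(self, i: int) -> ModelParams:
        """The i-th draw as a ModelParams point."""
        p = {k: float(v[i]) for k, v in self.params.items()}
        if self.model == "stationary":
            return ModelParams(alpha=0.0, t0=0.0, sigma=p["sigma"], epsilon=1.0,
                               sigma_obs=p["sigma_obs"], dt=self.dt,
                               beta_const=p["beta"])
        return ModelParams(alpha=p["alpha"], t0=p["t0"], sigma=p["sigma"],
                           epsilon=p["epsilon"], sigma_obs=p["sigma_obs"], dt=self.dt)

    def mean_params(self) -> ModelParams:
        """Posterior-mean point estimate as a ModelParams."""
        p = {k: float(v.mean()) for k, v in self.params.items()}
        if self.model == "stationary":
            return ModelParams(alpha=0.0, t0=0.0, sigma=p["sigma"], epsilon=1.0,
                               sigma_obs=p["sigma_obs"], dt=self.dt,
                               beta_const=np.clip(p["beta"], -1.0, 1.0))
        return ModelParams(alpha=p["alpha"], t0=p["t0"], sigma=p["sigma"],
                           epsilon=p["epsilon"], sigma_obs=p["sigma_obs"], dt=self.dt)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.params)


# ---------------------------------------------------------------------------
# the HMC machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """Settings of the joint HMC sampler.

    ``chains * draws_per_chain`` draws are returned, where ``draws_per_chain``
    is ``ceil(n_draws / chains)`` truncated back to ``n_draws`` in total.
    """

    chains: int = 4
    warmup: int = 1000
    target_accept: float = 0.8
    max_leapfrog: int = 40
    init_jitter: float = 0.05
    model: str = "time_varying"  # or "stationary"
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("time_varying", "stationary"):
            raise ValueError("model must be 'time_varying' or 'stationary'")
        if self.chains < 1 or self.warmup < 20 or self.max_leapfrog < 1:
            raise ValueError("invalid sampler settings")


class _JointModel:
    """Unconstrained-space joint density with analytic gradient.

    Coordinate layout: time-varying -> [log alpha, t0, log sigma,
    (logit-eps when sampled), (logit-sigma_obs when sampled), u_0..u_N];
    stationary -> [beta, log sigma, (logit-sigma_obs), u_0..u_N], with the
    path preconditioned as x = mu + s_x u.
    """

    def __init__(self, mu: np.ndarray, priors: PriorSpec, cfg: SamplerConfig):
        self.mu = np.asarray(mu, dtype=float)
        self.T = self.mu.size
        self.priors = priors
        self.kind = cfg.model
        self.dt = cfg.dt
        self.sample_eps = priors.samples_epsilon and self.kind == "time_varying"
        self.eps_fixed = (1.0 if self.kind == "stationary"
                          else None if self.sample_eps else float(priors.epsilon))
        self.sample_sobs = priors.samples_sigma_obs
        self.sobs_fixed = None if self.sample_sobs else float(priors.sigma_obs)
        self.s_x = priors.sigma_obs_value()
        self.ti = np.arange(self.T - 1) * self.dt
        n_theta = ((3 + int(self.sample_eps)) if self.kind == "time_varying" else 2) \
            + int(self.sample_sobs)
        self.n_theta = n_theta
        self.dim = n_theta + self.T

    # -- parameter packing ---------------------------------------------------

    def z0(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        pr = self.priors
        z = np.zeros(self.dim)
        k = 0
        if self.kind == "time_varying":
            z[0] = math.log(0.6745 * pr.alpha_scale)   # prior median of |N(0,s)|
            z[1] = pr.t0_mean
            z[2] = math.log(0.6745 * pr.sigma_scale)
            k = 3
            if self.sample_eps:
                lo, hi = pr.epsilon
                z[3] = logit(np.clip((1.0 - lo) / (hi - lo), 0.05, 0.95))  # eps ~ 1
                k = 4
        else:
            z[0] = pr.beta_mean
            z[1] = math.log(0.6745 * pr.sigma_scale)
            k = 2
        if self.sample_sobs:
            z[k] = 0.0  # midpoint of the uniform bounds
            k += 1
        z[:k] += jitter * rng.standard_normal(k)
        z[k:] += jitter * rng.standard_normal(self.T)
        return z

    def unpack(self, z: np.ndarray) -> Tuple[ModelParams, np.ndarray]:
        pr = self.priors
        if self.kind == "time_varying":
            alpha, t0 = math.exp(z[0]), z[1]
            sigma = math.exp(z[2])
            if self.sample_eps:
                lo, hi = pr.epsilon
                eps = lo + (hi - lo) * expit(z[3])
                k = 4
            else:
                eps = self.eps_fixed
                k = 3
            beta_const = None
        else:
            beta_const, sigma = float(z[0]), math.exp(z[1])
            alpha, t0, eps = 0.0, 0.0, 1.0
            k = 2
        if self.sample_sobs:
            olo, ohi = pr.sigma_obs
            sobs = olo + (ohi - olo) * expit(z[k])
            k += 1
        else:
            sobs = self.sobs_fixed
        x = self.mu + self.s_x * z[k:]
        params = ModelParams(alpha=alpha, t0=t0, sigma=sigma, epsilon=eps,
                             sigma_obs=sobs, dt=self.dt, beta_const=beta_const)
        return params, x

    # -- density and gradient ------------------------------------------------

    def logp_grad(self, z: np.ndarray) -> Tuple[float, np.ndarray]:
        pr, T = self.priors, self.T
        grad = np.empty_like(z)
        # guard against leapfrog excursions that overflow exp()
        if not np.all(np.isfinite(z)) or np.max(np.abs(z[:self.n_theta])) > 300.0:
            return -np.inf, grad
        if self.kind == "time_varying":
            za, t0, zs = z[0], z[1], z[2]
            alpha, sigma = math.exp(za), math.exp(zs)
            if self.sample_eps:
                ze = z[3]
                elo, ehi = pr.epsilon
                ew = ehi - elo
                p_e = expit(ze)
                if p_e <= 0.0 or p_e >= 1.0:  # saturated logit: zero Jacobian
                    return -np.inf, grad
                eps = elo + ew * p_e
                k = 4
            else:
                eps = self.eps_fixed
                k = 3
        else:
            beta0, zs = z[0], z[1]
            sigma = math.exp(zs)
            eps = 1.0
            k = 2
        if not 1e-10 < sigma < 1e10:  # leapfrog excursion; variance over/underflows
            return -np.inf, grad
        if self.sample_sobs:
            olo, ohi = pr.sigma_obs
            ow = ohi - olo
            p_o = expit(z[k])
            if p_o <= 0.0 or p_o >= 1.0:
                return -np.inf, grad
            sobs = olo + ow * p_o
            k_obs = k
            k += 1
        else:
            sobs = self.sobs_fixed
        u = z[k:]
        x = self.mu + self.s_x * u
        dt = self.dt

        xc, xn = x[:-1], x[1:]
        if self.kind == "time_varying":
            arg = alpha * eps * (self.ti - t0)
            beta = np.tanh(arg)
        else:
            beta = np.full(T - 1, beta0)
        om = xc * xc - 1.0
        f = -om * (xc - beta)
        fp = -(3.0 * xc * xc - 2.0 * beta * xc - 1.0)
        m = xc + eps * f * dt
        v = sigma * sigma * eps * dt
        inv_v = 1.0 / v
        r = xn - m
        rss = float(r @ r)
        e = self.mu - x  # = -s_x u

        logp = (-0.5 * (T - 1) * (_LOG_2PI + math.log(v)) - 0.5 * inv_v * rss
                - T * (0.5 * _LOG_2PI + math.log(sobs))
                - 0.5 * float(e @ e) / (sobs * sobs))

        # gradients wrt the path
        g_x = e / (sobs * sobs)
        dldm = r * inv_v
        g_x[1:] -= dldm
        g_x[:-1] += dldm * (1.0 + eps * dt * fp)
        grad[k:] = self.s_x * g_x

        S_v = -0.5 * (T - 1) * inv_v + 0.5 * inv_v * inv_v * rss
        dfdb = om

        if self.kind == "time_varying":
            sech2 = 1.0 - beta * beta
            common = dldm * (eps * dt) * dfdb * sech2
            g_alpha = float(common @ (eps * (self.ti - t0)))
            g_t0 = float(common.sum()) * (-alpha * eps)
            # priors
            logp += _halfnormal_logpdf(alpha, pr.alpha_scale)
            g_alpha += -alpha / pr.alpha_scale ** 2
            logp += -0.5 * _LOG_2PI - math.log(pr.t0_sd) \
                - 0.5 * ((t0 - pr.t0_mean) / pr.t0_sd) ** 2
            g_t0 += -(t0 - pr.t0_mean) / pr.t0_sd ** 2
            # transforms + Jacobians
            grad[0] = g_alpha * alpha + 1.0
            logp += za
            grad[1] = g_t0
            if self.sample_eps:
                g_eps = float(dldm @ (f * dt + eps * dt * dfdb * sech2 * alpha
                                      * (self.ti - t0))) + S_v * sigma * sigma * dt
                logp += -math.log(ew)
                grad[3] = g_eps * ew * p_e * (1.0 - p_e) + (1.0 - 2.0 * p_e)
                logp += math.log(ew * p_e * (1.0 - p_e))
            zs_slot = 2
        else:
            g_beta = float(dldm @ (eps * dt * dfdb))
            logp += -0.5 * _LOG_2PI - math.log(pr.beta_sd) \
                - 0.5 * ((beta0 - pr.beta_mean) / pr.beta_sd) ** 2
            g_beta += -(beta0 - pr.beta_mean) / pr.beta_sd ** 2
            grad[0] = g_beta
            zs_slot = 1

        g_sigma = S_v * 2.0 * sigma * eps * dt
        logp += _halfnormal_logpdf(sigma, pr.sigma_scale)
        g_sigma += -sigma / pr.sigma_scale ** 2
        grad[zs_slot] = g_sigma * sigma + 1.0
        logp += z[zs_slot]

        if self.sample_sobs:
            g_sobs = -T / sobs + float(e @ e) / sobs ** 3
            logp += -math.log(ow)
            grad[k_obs] = g_sobs * ow * p_o * (1.0 - p_o) + (1.0 - 2.0 * p_o)
            logp += math.log(ow * p_o * (1.0 - p_o))

        return logp, grad


def _find_initial_step(model: _JointModel, z: np.ndarray, lp: float,
                       g: np.ndarray, inv_mass: np.ndarray,
                       rng: np.random.Generator) -> float:
    """Heuristic: tune a step size whose one-step accept prob crosses 0.5."""
    step = 0.1
    p = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = -lp + 0.5 * float(p * p @ inv_mass)
    direction = 0
    for _ in range(60):
        p1 = p + 0.5 * step * g
        z1 = z + step * inv_mass * p1
        lp1, g1 = model.logp_grad(z1)
        if np.isfinite(lp1):
            p1 = p1 + 0.5 * step * g1
            h1 = -lp1 + 0.5 * float(p1 * p1 @ inv_mass)
            log_accept = h0 - h1
        else:
            log_accept = -np.inf
        new_dir = 1 if log_accept > math.log(0.5) else -1
        if direction == 0:
            direction = new_dir
        elif new_dir != direction:
            break
        step *= 2.0 if new_dir == 1 else 0.5
        if step < 1e-12 or step > 1e3:
            break
    return step


def _adapt_windows(n_warmup: int) -> Tuple[int, int, list]:
    """(init_buffer, term_buffer, metric window sizes) a la windowed adaptation."""
    init_buf = max(20, min(75, n_warmup // 8))
    term_buf = max(20, min(50, n_warmup // 10))
    middle = n_warmup - init_buf - term_buf
    windows, w = [], 25
    while middle > 0:
        if middle < 2 * w:
            windows.append(middle)
            middle = 0
        else:
            windows.append(w)
            middle -= w
            w *= 2
    return init_buf, term_buf, windows


def _run_chain(model: _JointModel, cfg: SamplerConfig, n_warmup: int,
               n_keep: int, rng: np.random.Generator):
    dim = model.dim
    z = model.z0(rng, cfg.init_jitter)
    lp, g = model.logp_grad(z)
    if not np.isfinite(lp):
        raise RuntimeError("failed to initialize within prior support")
    inv_mass = np.ones(dim)
    step = _find_initial_step(model, z, lp, g, inv_mass, rng)

    # dual-averaging state
    def fresh_da(step0: float):
        return {"mu": math.log(10.0 * step0), "log_bar": math.log(step0),
                "h": 0.0, "m": 0}

    da = fresh_da(step)
    gamma, t0_da, kappa = 0.05, 10.0, 0.75
    init_buf, term_buf, windows = _adapt_windows(n_warmup)
    window_ends = list(np.cumsum([init_buf] + windows))
    window_samples: list = []

    draws = np.empty((n_keep, dim))
    logps = np.empty(n_keep)
    n_accept, n_total = 0, 0

    for it in range(n_warmup + n_keep):
        n_leap = int(rng.integers(1, cfg.max_leapfrog + 1))
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * float(p * p @ inv_mass)
        z_new, g_new, lp_new = z, g, lp
        p_new = p + 0.5 * step * g
        diverged = False
        for leap in range(n_leap):
            z_new = z_new + step * inv_mass * p_new
            lp_new, g_new = model.logp_grad(z_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            if leap < n_leap - 1:
                p_new = p_new + step * g_new
        if not diverged:
            p_new = p_new + 0.5 * step * g_new
            h1 = -lp_new + 0.5 * float(p_new * p_new @ inv_mass)
            delta_h = h0 - h1
            if not np.isfinite(delta_h) or delta_h < -1000.0:
                diverged = True
        accept_prob = 0.0 if diverged else min(1.0, math.exp(min(0.0, delta_h)))
        if not diverged and rng.random() < accept_prob:
            z, lp, g = z_new, lp_new, g_new

        if it < n_warmup:
            # dual averaging toward the target acceptance
            da["m"] += 1
            m = da["m"]
            eta_h = 1.0 / (m + t0_da)
            da["h"] = (1.0 - eta_h) * da["h"] + eta_h * (cfg.target_accept - accept_prob)
            log_step = da["mu"] - math.sqrt(m) / gamma * da["h"]
            eta = m ** (-kappa)
            da["log_bar"] = eta * log_step + (1.0 - eta) * da["log_bar"]
            step = math.exp(log_step)
            # metric adaptation windows
            if it >= init_buf and it < n_warmup - term_buf:
                window_samples.append(z.copy())
            if (it + 1) in window_ends[1:] and window_samples:
                samp = np.asarray(window_samples)
                n_s = samp.shape[0]
                var = samp.var(axis=0)
                inv_mass = (n_s / (n_s + 5.0)) * var + 1e-3 * (5.0 / (n_s + 5.0))
                window_samples = []
                step = _find_initial_step(model, z, lp, g, inv_mass, rng)
                da = fresh_da(step)
            if it == n_warmup - 1:
                step = math.exp(da["log_bar"])
        else:
            j = it - n_warmup
            draws[j] = z
            logps[j] = lp
            n_accept += accept_prob
            n_total += 1

    return draws, logps, n_accept / max(n_total, 1)


def _diagnostics(chain_params: Dict[str, np.ndarray]) -> Dict[str, Dict[str, float]]:
    """Split R-hat and bulk ESS per parameter from (chain, draw) arrays."""
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in chain_params.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    out = {}
    for name in chain_params:
        out[name] = {"rhat": float(rhat[name].values),
                     "ess": float(ess[name].values)}
    return out


def sample_posterior(mu_path, priors: PriorSpec, n_draws: int = 4000,
                     seed: int = 0, config: Optional[SamplerConfig] = None
                     ) -> PosteriorDraws:
    """Sample the joint posterior over parameters and the latent path.

    Runs ``config.chains`` independent HMC chains (deterministic given
    ``seed``), returns ``n_draws`` total post-warmup draws, and attaches split
    R-hat / effective-sample-size diagnostics; a ``ConvergenceWarning`` is
    issued when any split R-hat exceeds 1.05.
    """
    cfg = config or SamplerConfig()
    values = mu_path.values if hasattr(mu_path, "values") else np.asarray(mu_path, dtype=float)
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("embedding contains non-finite values")
    if values.size < 30:
        raise ValueError("embedding must contain at least 30 samples")

    model = _JointModel(values, priors, cfg)
    per_chain = int(math.ceil(n_draws / cfg.chains))
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), 2 ** 17 + 29])
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(cfg.chains)]

    all_draws, accepts = [], []
    for rng in chain_rngs:
        draws, _, acc = _run_chain(model, cfg, cfg.warmup, per_chain, rng)
        all_draws.append(draws)
        accepts.append(acc)
    z_chains = np.asarray(all_draws)  # (chains, per_chain, dim)

    # constrained parameters per chain for diagnostics
    if cfg.model == "time_varying":
        names = ["alpha", "t0", "sigma"]
        if priors.samples_epsilon:
            names.append("epsilon")
        store = ["alpha", "t0", "sigma", "epsilon", "sigma_obs"]
    else:
        names = ["beta", "sigma"]
        store = ["beta", "sigma", "sigma_obs"]
    if priors.samples_sigma_obs:
        names.append("sigma_obs")
    chain_params: Dict[str, np.ndarray] = {n: np.empty(z_chains.shape[:2]) for n in names}
    flat_params: Dict[str, list] = {n: [] for n in store}
    paths, ljs = [], []
    for c in range(cfg.chains):
        for d in range(per_chain):
            params, x = model.unpack(z_chains[c, d])
            for n in names:
                chain_params[n][c, d] = _param_value(params, n)
            for n in flat_params:
                flat_params[n].append(_param_value(params, n))
            paths.append(x)
            ljs.append(log_joint(params, x, values, priors))

    diagnostics = _diagnostics(chain_params)
    bad = {n: d["rhat"] for n, d in diagnostics.items() if d["rhat"] > 1.05}
    if bad:
        warnings.warn(f"split R-hat above 1.05 for {bad}; chains may not have "
                      "converged", ConvergenceWarning, stacklevel=2)

    total = cfg.chains * per_chain
    keep = slice(0, n_draws) if total >= n_draws else slice(0, total)
    params_out = {n: np.asarray(v)[keep] for n, v in flat_params.items()}
    return PosteriorDraws(
        params=params_out,
        latent_paths=np.asarray(paths)[keep],
        n_draws=params_out[names[0]].size,
        seed=int(seed),
        diagnostics=diagnostics,
        log_joint_values=np.asarray(ljs)[keep],
        priors=priors,
        model=cfg.model,
        dt=cfg.dt,
        chains=cfg.chains,
        accept_rate=float(np.mean(accepts)),
    )


def _param_value(params: ModelParams, name: str) -> float:
    if name == "beta":
        return float(params.beta_const)
    if name == "epsilon":
        return params.epsilon
    return float(getattr(params, name))
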