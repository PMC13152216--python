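# Methods

## Model

The sleep-onset state is a scalar `x(t)` moving in the cubic double-well
force field `f(x; β) = −(x + 1)(x − β)(x − 1)` with additive white noise of
strength `σ`.  For any barrier position `β ∈ (−1, 1)` the equilibria are
`x = ±1` (stable; the linearized rates are `−2(1 ∓ β)`) and `x = β`
(unstable).  The sleep drive `β(t) = tanh(α(t − t0))` tilts the landscape
from wake-favouring (`β ≈ −1`) to sleep-favouring (`β ≈ +1`); `α` has units
of inverse model time, `t0` of model time.  Large `σ` produces repeated
noise-driven crossings ("flickering") while the barrier is low; large `α`
shortens the window in which crossings are possible.

Forward simulation uses Euler–Maruyama with an internal step of `dt/substeps`
(default `substeps = 10`); states are recorded on the observation grid.  The
simulator is deterministic given `(params, x0, seed)` and raises an
integration error naming the step at which a state became non-finite (which
does not occur for the parameter ranges used here; no state clipping is
applied).

## Observation model and inference

The embedding series `μ_0:N` is treated as the latent path observed through
Gaussian noise, `μ_i = x_i + η_i`, `η_i ~ N(0, σ_obs²)`.  Between
observations the transition density is the one-step Euler kernel

```
m_i = x_i + ε f(x_i; β_i) Δt ,   v = σ² ε Δt ,   β_i = tanh(α ε (t_i − t0)),
```

with `t_i = i Δt` the observation-index clock and `ε` a time-scale factor
absorbing the unknown ratio between the recording clock and the model clock.
The joint log posterior is the prior plus the sum of observation and
transition log densities (`log_joint`), and sampling targets parameters and
path jointly.

Priors (simulated context): `α ~ HalfNormal(1)`, `t0 ~ Normal(50, 10)`,
`σ ~ HalfNormal(2)`, `ε` fixed at 1, `σ_obs` fixed at `1e−5` (the sampled
path is pinned to the observed trajectory).  Experimental context:
`t0 ~ Normal(N/2, N/4)` with `N` the embedding length,
`ε ~ Uniform(0.1, 5)`, `σ_obs ~ Uniform(0.1, 0.4)`, others unchanged.  `ε`
and `σ_obs` are sampled only in the experimental context: in simulation
studies the generator and the likelihood share one clock and the observation
noise is part of the design, so freeing them would only dilute the
identifiable parameters.  A stationary-landscape variant (fixed `β` with a
`Normal(0, 1)` prior, `ε = 1`) supports the fixed-grid recovery study.

### Sampler

No gradient-based probabilistic-programming sampler fits this model
off-the-shelf in our dependency set, and the ~1000-dimensional joint
(θ, path) space is outside the comfortable regime of ensemble samplers, so
the package ships its own Hamiltonian Monte Carlo implementation:

* **Parameterization.** Positive parameters on log scale, interval-bounded
  parameters on logit scale, each with its Jacobian correction; the path is
  sampled centered but preconditioned as `x = μ + s_x u` with `s_x` the
  observation-noise scale, so every coordinate is O(1).  A non-centered
  path recursion was rejected: with the observation noise pinning the path,
  centered geometry is nearly white, and the recursion would serialize the
  otherwise fully vectorized gradient.
* **Gradients** of the log joint are analytic and vectorized over the path;
  they are verified against finite differences in the test suite, and the
  posterior means are cross-checked against an independent ensemble sampler
  (emcee) on the path-pinned problem.
* **Adaptation.** Dual-averaging step size (target acceptance 0.8) and a
  windowed diagonal metric estimated from warmup draws, in the style of
  Stan's adaptation schedule; trajectory lengths are jittered uniformly up
  to `max_leapfrog` (default 40).  Leapfrog excursions that overflow the
  transforms are treated as divergences (rejected).
* **Defaults.** 4 chains × 1000 warmup and 1000 kept draws = 4000 posterior
  draws, matching the posterior predictive trajectory count used throughout.
  Split R-hat and bulk ESS are computed per parameter (arviz); any split
  R-hat above 1.05 raises a convergence warning.  Everything is
  deterministic given the seed.

## Embedding pipeline

EEG preprocessing: order-4 Butterworth band-pass 0.5–30 Hz applied
forward-backward (zero phase), resampling to 100 Hz.  Spectrogram: complex
Morlet wavelet (bandwidth 1, center frequency 1.5) evaluated at 200 equally
spaced frequencies in [0.5, 20] Hz.

The sleep-onset window is found from the per-column ratio of mean delta-band
(0.5–4 Hz) to mean alpha-band (8–12 Hz) amplitude: the transition start is
the first contiguous ratio-above-1 run longer than one minute, the end the
first run longer than two minutes searched from the start onward; the window
pads the transition by 200 s on each side (truncated with a warning at the
recording edges) and anchors "wake" and "sleep" as its first and last 60 s.

The wake and sleep modes are the leading left-singular vectors of the
unit-column-normalized segment submatrices, oriented so their entry sum is
positive.  For the projection, each *frequency row* of the window submatrix
is normalized to unit norm, and each column of the normalized matrix is
projected onto `(U_wake − U_sleep)`.  Row (rather than column)
normalization is deliberate: row factors are constant in time, so the
projection of a two-mode mixture spectrogram is *exactly affine* in the
mixture weight, which makes projection and reconstruction
(`w·U_wake + (1−w)·U_sleep`, `w = clip((x+1)/2, 0, 1)`) a consistent round
trip; per-column normalization would make the projection provably nonlinear
in the weight.  The projected series is Gaussian-smoothed (default 1 s
standard deviation), decimated by 10, and affinely scaled so the
wake-segment mean is +1 and the sleep-segment mean −1 (the affine anchoring
generalizes a fixed `2μ − 1` map and is well defined for any input with
wake/sleep contrast).  A rank-2 SVD diagnostic of the full window verifies
the expected structure: the leading temporal mode tracks total power, the
second tracks the transition coordinate.

## Synthetic data

The generator produces subjects with known ground truth at the simulation
study conditions:

* **Fixed landscape** (stationary): `β ∈ {−0.8, −0.6, …, 0.8}` ×
  `σ ∈ {0.2, 0.3, …, 1.0}`, initial state 0.
* **Time-varying**: `α` over 10 log-spaced values in [0.05, 1] plus 1.5,
  `t0 ∈ {40, 50, 60}`, `σ ∈ {0.2, …, 1.0}`, initial state 1.

**Observation step.**  The simulated scenarios use `Δt = 0.1` model-time
units over a 100-unit horizon (1001 samples).  This is a deliberate
numerical choice: the drift's linearized rate at a stable well reaches
`2(1 + |β|) ≈ 4` per model-time unit, so a one-step Euler transition kernel
is only dynamically consistent for steps well below the inverse rate —
at a unit step its self-consistent generative process is numerically
explosive and fits against finely integrated data degenerate.  At
`Δt = 0.1` (rate × step = 0.4) the kernel is faithful and recovery behaves
as intended.  Embeddings carry Gaussian observation noise exactly per the
observation model; spectrograms are convex mixtures of an alpha-peaked wake
mode (Gaussian bump at 10 Hz over a small 1/f floor) and a delta-dominated
1/f sleep mode, with optional multiplicative power noise; toy time-domain
EEG is an amplitude-modulated mixture of 10 Hz and 2 Hz carriers (enough to
exercise filtering and band-ratio logic, not claimed physiological).
Per-cell seeds derive from the master seed and the cell indices, so any
grid subset is reproducible in isolation.

What the generator does *not* emulate: spindles, K-complexes, artifacts,
non-stationary spectra within a state, multi-channel structure.  Green tests
therefore demonstrate the correctness of the machinery and the behavior of
the method under its own assumptions, not performance on real recordings.

## Evaluation

* **Posterior predictive**: one forward trajectory per posterior draw,
  starting at the first observed value, using the same one-step Euler kernel
  that defines the likelihood (so the check targets exactly the fitted
  model).  Scores: pooled KL divergence `KL(observed ‖ simulated)` on shared
  50-bin histograms with `1e−10` regularization (direction and estimator are
  a package choice), and pointwise RMSE.  Representatives: argmin-KL,
  argmin-RMSE (ties to the lowest index), and the trajectory of the draw
  maximizing the joint log density; per-timepoint 10%/90% bands use
  lower/higher quantile interpolation so two trajectories give their
  envelope.
* **Likelihood decomposition**: per-draw, per-step observation and
  transition log densities evaluated on the sampled path, averaged across
  draws; modes summarized by Gaussian KDE (Silverman bandwidth, 512-point
  grid).
* **Switch counting**: moving-average smoothing, sign state with a ±0.1
  hysteresis dead band, and a 50-sample commitment rule (a state must hold
  50 consecutive samples to count; the first committed state is the
  baseline).  For switching statistics of simulated trajectories the
  smoothing window is 2 model-time units.

## Known limitations

* `α` is only weakly identified from a single trajectory once the drive is
  steep: the likelihood is nearly flat in `α` above roughly 0.2–0.4 at
  moderate noise (`σ = 0.5`), because a steep ramp compresses the
  informative transition into a few samples.  Posterior means then shrink
  toward the prior scale — small `α` is overestimated, large `α`
  underestimated, with substantial trajectory-to-trajectory spread — while
  rank ordering of the per-value *means* emerges only with many replicates.
  `σ` and `t0` do not share this problem.
* The one-step Euler kernel is first-order: even at `Δt = 0.1` the fitted
  `σ` carries a small (≈ 5–10%) downward discretization bias at the largest
  noise levels.
* The embedding assumes a two-mode (rank-2 in the global sense) spectral
  structure; broadband power fluctuations within a state are treated as
  residual variability.
* Experimental-context fits depend on the SOP-window heuristic; recordings
  without a sustained delta/alpha reversal raise a no-transition error
  rather than producing a window.
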