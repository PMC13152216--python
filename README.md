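# sopdyn — stochastic bistable dynamics of the sleep-onset period

`sopdyn` models the wake-to-sleep transition seen in single-channel EEG as a
noisy particle in a slowly tilting double-well landscape, and fits that model
to a *single* recording by joint Bayesian inference over its parameters and
latent state path.  It is written for computational neuroscientists and sleep
researchers who want mechanistic, subject-level descriptors of sleep-onset
dynamics (drive steepness, onset time, intrinsic noise) rather than discrete
sleep stages.

## The model

The latent sleep-onset state `x(t)` obeys a cubic Langevin equation whose
unstable barrier is moved by a slowly varying sleep drive `β(t)`:

```
dx = −(x + 1)(x − β(t))(x − 1) dt + σ dW ,        β(t) = tanh(α (t − t0))
```

The stable equilibria sit at `x = +1` (wake) and `x = −1` (sleep) for every
drive value in (−1, 1); `α` sets how fast the landscape tilts toward sleep,
`t0` when it starts, and `σ` the intrinsic fluctuation strength that produces
the characteristic back-and-forth "flickering" during sleep onset.

The observable is a one-dimensional *transition coordinate* `μ(t)` obtained
from the EEG: a complex-Morlet wavelet spectrogram (200 bins, 0.5–20 Hz) is
reduced by projecting it onto the difference of the leading SVD modes of its
stable-wake and stable-sleep segments, scaled so wake maps to +1 and sleep to
−1.  Inference assumes

```
μ_i = x_i + η_i ,                       η_i ~ N(0, σ_obs²)
x_{i+1} | x_i ~ N(x_i + ε f(x_i; β_i) Δt ,  σ² ε Δt)
```

(one-step Euler–Maruyama transition density, time-scale factor `ε` aligning
the model clock with the recording clock), and samples the joint posterior of
`θ = (α, t0, σ, ε, σ_obs)` and the latent path `x_0:N` with Hamiltonian Monte
Carlo using analytic gradients.  Model evaluation uses posterior predictive
checks (pooled Kullback–Leibler divergence and RMSE over forward-simulated
trajectories), a per-timepoint observation/transition likelihood
decomposition, and robust hysteresis switch counting.

## Worked example

Simulate one synthetic subject at known parameters, fit it, and run the
posterior predictive check:

```python
import sopdyn as sd

params = sd.ModelParams(alpha=0.3, t0=50.0, sigma=0.6, sigma_obs=1e-5, dt=0.1)
subject = sd.synthetic_embedding(params, n_obs=1001, x0=1.0, seed=8)

priors = sd.default_priors("simulated")
config = sd.SamplerConfig(chains=2, warmup=400, dt=0.1)
draws = sd.sample_posterior(subject.embedding, priors, n_draws=1000,
                            seed=1, config=config)
for name in ("alpha", "t0", "sigma"):
    lo, hi = draws.quantile(name, [0.05, 0.95])
    print(f"{name:>6}: posterior mean {draws.mean(name):6.3f}   "
          f"90% CI [{lo:6.3f}, {hi:6.3f}]")

trajs = sd.posterior_predictive(draws, subject.embedding, n_traj=1000, seed=2)
ppc = sd.select_representatives(trajs, draws, subject.embedding)
print(f"min KL {ppc.kl_values.min():.4f} (mode {ppc.kl_mode:.4f}), "
      f"min RMSE {ppc.rmse_values.min():.4f} (mode {ppc.rmse_mode:.4f})")
```

prints

```
 alpha: posterior mean  0.977   90% CI [ 0.294,  1.908]
    t0: posterior mean 49.782   90% CI [48.003, 51.402]
 sigma: posterior mean  0.502   90% CI [ 0.485,  0.519]
min KL 0.0545 (mode 0.1505), min RMSE 0.2815 (mode 0.3410)
```

The noise level `σ` and the onset `t0` are recovered sharply from the single
trajectory; the drive steepness `α` is recovered with the broad posterior
typical of this model — its *ordering* across subjects is informative, its
point value saturates for steep drives (see `docs/methods.md`).  The KL/RMSE
values summarize how closely forward simulations from the posterior
reproduce the observed trajectory's value distribution and time course.

The same pipeline is available from the shell via the `sop` command
(`sop simulate`, `sop embed`, `sop fit`, `sop ppc`, `sop switches`,
`sop synth`, `sop recover`, `sop consistency`); run `sop --help`.

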