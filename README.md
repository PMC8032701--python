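# actihsmm

Zero-inflated Poisson hidden semi-Markov models (ZIP-HSMM) for minute-epoch
activity counts, with two-stage population inference on treatment effects.

## The problem

Collar or wrist accelerometers integrate movement into one nonnegative integer
count per minute.  In chronic-pain studies (the motivating setting is a
randomized, double-blind, placebo-controlled crossover trial of an NSAID in
animals with osteoarthritis-associated pain) these series are extremely
sparse — typically more than 70% of minutes are exact zeros — and heavy
tailed, and treatment may change *how* a subject is active (more intense
bouts, better rest) without moving the overall mean.  Averaging counts per
period and running an ANOVA throws that structure away.

`actihsmm` instead models the minute-by-minute series directly: each subject
moves through `M` latent activity states (resting, walking, running, ...)
ordered by intensity, stays in a state for an explicitly modeled dwell time,
and emits counts from a state-specific distribution.  Treatment effects are
estimated *within* each latent state, then aggregated across subjects.

## The model

For subject *i* with latent state `S_t ∈ {1..M}`, treatment covariates
`x_t ∈ R^q`, environment covariates `z_t ∈ R^p` (night, weekend), and counts
`Y_t`:

* **Emissions** — state 1 is zero-inflated Poisson, states 2..M Poisson:

  `logit p_t = b_00 + b_10' x_t + γ_0' z_t` (zero-inflation weight, state 1 only)

  `log λ_t(m) = b_0m + b_1m' x_t + γ_m' z_t`

  with ordering constraints `b_0,m+1 > b_0,m`, `b_1,m+1 ≥ b_1,m`,
  `γ_m+1 ≥ γ_m`, so intensities are monotone in the state index and states
  are comparable across subjects.

* **Dwell times** — an accelerated failure time model discretized to whole
  minutes: with acceleration `a = exp(c_m' x + η_m' z)` and base density
  `f_m` (Weibull default, gamma selectable),
  `r_m(v) ∝ a ∫_v^{v+1} f_m(a u) du`, truncated and renormalized to
  `v ∈ {1..D_max}`.  The final dwell of a series is right-censored through
  the survivor function.

* **Transitions** — conditional on leaving state `m`, a multinomial logit
  `Q(m,l) ∝ exp(d_ml' x + ϱ_ml' z)` over destinations `l ≠ m`
  (self-transitions are structurally excluded; dwell lengths belong to the
  duration model).

* **Two-stage population inference** — each subject's parameters are
  estimated by maximizing the exact explicit-duration forward likelihood
  (complexity `O(T·M·(M+D_max))`, analytic gradients); `M` is chosen by BIC.
  Subject-level treatment coefficients `b̂_1m,i` are then regressed on
  baseline covariates `W_i` (sex, body condition, age, OA score, sequence):
  `E(b_1m,i | W_i) = Ω_m0 + Ω_m1 W_i`, by least squares with the
  heteroskedasticity-consistent sandwich covariance
  `(X'X)⁻¹ X' diag(e²) X (X'X)⁻¹`, valid as `n/T → 0`.  Wald z tests give
  per-state p-values, and a log-scale coefficient `b` is reported as a
  percent effect size `100·b`.

## Worked example

```python
import numpy as np
from actihsmm import (StudyDesign, ZeroInflatedPoissonHSMM,
                      effect_size_percent, wald_test)
from actihsmm.simulate import default_paper_like_truth, simulate_study

# 1. simulate a small crossover study from the shipped 6-state truth
truth = default_paper_like_truth()
series, baseline, truth = simulate_study(
    truth, StudyDesign(n_subjects=4), seed=0, total_minutes=7 * 1440)
y = np.concatenate([s.y for s in series])
print(f"zero minutes: {100 * np.mean(y == 0):.1f}%   "
      f"75th percentile: {np.percentile(y, 75):.0f}   max: {y.max()}")

# 2. fit one subject with a 2-state model and decode it
est = ZeroInflatedPoissonHSMM(M=2, D_max=60, q=1, p_dim=2,
                              n_restarts=1, random_state=0).fit(series[0])
print(f"loglik = {est.log_likelihood_:.1f}   BIC = {est.bic_:.1f}")
path = est.decode(series[0])
print(f"decoded state-1 share: {100 * np.mean(path.states == 1):.1f}%")

# 3. a Wald test from a published-style (estimate, SE) pair
z, p = wald_test(0.0914, 0.0351)
print(f"effect {effect_size_percent(0.0914):.2f}%  z = {z:.3f}  p = {p:.4f}")
```

Output from this exact script:

```
zero minutes: 80.2%   75th percentile: 0   max: 230
loglik = -26058.0   BIC = 52318.8
decoded state-1 share: 93.0%
effect 9.14%  z = 2.604  p = 0.0092
```

The simulated data show the calibrated regime (three quarters of minutes
zero, heavy right tail); the 2-state fit separates rest from activity; the
Wald line reproduces a published-style per-state treatment effect: a 0.0914
log-intensity coefficient is a 9.14% increase in mean activity in that state,
significant at the 1% level.

A `typer` CLI wraps the same pipeline:

```bash
actihsmm simulate --seed 1 --out sim/
actihsmm fit --activity sim/activity.csv --config cfg.yaml --out fits/
actihsmm decode --activity sim/activity.csv --fits fits/ --out decode/
actihsmm pop-infer --fits fits/ --out pop/
actihsmm report --fits fits/ --out report/
```

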