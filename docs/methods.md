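# Methods

This note records the modeling assumptions, parameter conventions, numerical
choices, and limitations of `actihsmm`.  Notation follows the README.

## Model structure and conventions

**Latent process.** Subjects evolve through `M` latent activity states.  The
joint law is explicit-duration semi-Markov: an initial state drawn from `δ`,
an integer dwell length drawn from the state's duration pmf, then a jump to a
*different* state from the multinomial-logit transition kernel.
Self-transitions are structurally excluded — the printed softmax of the
transition model is ambiguous about whether same-state terms are normalized
away, and we resolve it by zeroing the diagonal and renormalizing over the
remaining destinations, with the lowest-index allowed destination as the
reference category (coefficients fixed at zero) for identifiability.  A
consequence worth knowing: the transition logits carry no intercept, so at
reference covariates (`x = z = 0`) every allowed destination is equally
likely.

**Covariate timing within a dwell.** Emission covariates are read every
minute; duration covariates are frozen at the minute the dwell begins;
transition covariates are read at the minute the jump occurs (the last minute
of the old dwell).  Time-indexed models do not resolve within-dwell covariate
change on their own; this convention is applied consistently in the
likelihood, the Viterbi recursion, and the simulator, so all three describe
the same generative law.

**Emissions.** Zero inflation is confined to state 1 (the resting state):
states 2..M are plain Poisson.  The zero-inflated pmf uses the Poisson factor
`exp(-λ)`; a mixture with `exp(+λ)` would not normalize.  Ordering
constraints (`b_0` strictly increasing; slope columns nondecreasing) make
intensities monotone in the state index for every covariate value of a
binary design, which is what lets states be aligned across subjects by rank
with no post-hoc label matching.

**Dwell distributions.** The base density family is Weibull by default
(gamma selectable via `ModelConfig.duration_family`); both are closed under
the AFT time rescaling.  The AFT regression carries no intercept — it is
absorbed by the per-state scale.  Durations are whole minutes `v ∈
{1..D_max}`: the base-distribution mass of `[a·v, a·(v+1))` is truncated and
renormalized to that support, which realizes a finite-support duration
assumption.  `D_max` defaults to 360 minutes — far beyond plausible
single-behavior bouts at minute resolution while bounding the `O(T·M·(M +
D_max))` recursion cost.  Shape-1 Weibull dwells make the model collapse to
an ordinary HMM (geometric dwells); the test suite exploits this as an
independent oracle.

**Initial distribution.** Estimating `δ` "nonparametrically from decoded
state frequencies" is circular for a single sequence, so by default `δ` is
fixed uniform during optimization and excluded from the BIC parameter count;
an optional one-step re-estimation from the Viterbi path
(`reestimate_delta=True`) is provided, after which the likelihood and BIC
are recomputed at the updated `δ`.

**Right censoring.** The final dwell of every series is censored at `T`
through the duration survivor function, in the likelihood and in Viterbi.
Without it the likelihood systematically penalizes states with long dwells
near the end of the series.

## Estimation

**Subject level.** The exact forward likelihood is maximized directly
(no EM) over an unconstrained reparameterization: strictly increasing
intercepts via exponential-map increments, nondecreasing slopes via squared
increments (equality exactly representable, matching the strict/weak
constraint pair), probabilities via softmax, positive shapes and scales via
exponentials.  The inverse map is total — any real vector yields a valid
parameter set — so the optimizer is genuinely unconstrained.  A guard based
on `nextafter` preserves strict intercept ordering even when an increment
underflows.

The forward pass runs in the probability domain with per-minute rescaling
(emissions pre-normalized by their per-minute maximum), making the hot loop
pure multiply-add.  Gradients are analytic via Fisher's identity: a backward
pass reusing the forward normalizers yields posterior state occupancies,
dwell statistics and jump counts, which weight closed-form component scores
(the gamma-family shape derivative differentiates the incomplete gamma
function by a small central difference).  The analytic score is verified
against central finite differences in the test suite; it makes one
gradient step cost about three likelihood evaluations instead of
`n_params + 1`.

**Optimizer defaults.** L-BFGS-B with `ftol = 1e-9` (relative), `gtol =
1e-5`, memory `maxcor = 30`, at most 2,000 iterations, and 5 seeded restarts
(the first from a data-driven initialization: quantile-group means of the
positive counts for the intensity intercepts, the observed zero fraction for
the zero-inflation logit; slope increments start slightly off zero because
the squared-increment map has a stationary point exactly at a tie).  Two of
these defaults deserve their rationale:

* `ftol = 1e-9` rather than a looser relative tolerance: the log-likelihood
  magnitude grows with `T`, so at `T = 5,000` a relative `1e-6` translates to
  an absolute tolerance of ~0.01 and halts while weakly identified
  coefficients — notably the state-1 treatment effect, which trades off
  against the zero-inflation logit — are still moving.
* `maxcor = 30`: the same trade-off makes the surface ill-conditioned, and
  the larger curvature memory roughly halves the iteration count.

Fits are deterministic given (data, `random_state`); restart `k` perturbs
the data-driven start with seeded Gaussian noise.  Non-convergence across
restarts is flagged (`converged_ = False`), never raised, and flagged fits
are excluded (with a report) from the second stage.

**Model size.** `M` is selected by minimum BIC, `-2·loglik + j·ln T` with
`j` the count of optimized parameters; ties break toward smaller `M`;
per-candidate failures are recorded in the sweep table without aborting.

**Population level.** Subject-level treatment coefficients are stacked by
state rank and regressed on `[1, W]` per coefficient, exploiting the
Kronecker block structure of the stacked design.  The covariance is the
plain HC0 sandwich (no small-sample correction), exactly the form whose
asymptotic validity holds as `n, T → ∞` with `n/T → 0`; residuals absorb
both between-subject heterogeneity and first-stage estimation noise, which
is why neither needs its own model.  Baseline covariates are centered by
default so the reported intercept is the population-average effect;
centering provably moves only the intercept, never slopes or their standard
errors.  For *coverage of a truth intercept* the uncentered parameterization
must be used (the centered intercept targets the average effect at the
sample mean of `W`, a different estimand); the shipped coverage experiment
does this.  Reported percent effect sizes use the `100·b` convention for a
log-scale coefficient `b`; the exponential alternative `100·(e^b - 1)` is
available behind an explicit flag and never silently substituted.  P-values
are unadjusted for multiplicity across states.

**Viterbi.** The max-product analogue of the forward recursion over dwell
segmentations, with the same censored final dwell.  Ties break toward the
lower state index, then the shorter dwell.  Decoded paths feed the
time-in-state occupancy table and the optional `δ` re-estimation.

**Model fit check.** The quantile check simulates a long trajectory
(default 10×T) from the fitted model with the observed covariate schedule
recycled and pairs model count quantiles with empirical ones — with >70%
zeros, both sides of the pairing are zero up to at least the 75th
percentile, so only the upper tail is informative.

## The synthetic-data generator

The generator emulates the statistical structure the model assumes, at the
study design of an 11-week crossover (2 baseline weeks, treatment weeks 3–5,
washout 6–8, crossed treatment 9–11; 1,440 one-minute epochs per day; night
defined as 18:00–06:00, configurable, since no standard definition exists;
weekends from a Monday-start calendar).  Treatment-coefficient families
follow the linear hierarchy `coef = intercept + slope'W + noise` on the
natural scale, projected onto the ordering cone by isotonic regression — a
no-op when population values are separated relative to the noise scale, and
an error (advising a smaller noise scale) when the mean projection
displacement exceeds it.  Heterogeneity in intensity intercepts and dwell
scales acts on the unconstrained scale (shifts of log increments and log
scales), so realized parameters are always valid.  Reproducibility: subject
`i` draws from `default_rng([master_seed, i + 1])`, the baseline table from
`default_rng([master_seed, 0])`.

The shipped 6-state truth (`default_paper_like_truth`) is calibrated so
simulated data reproduce the descriptive regime of minute-epoch cat
accelerometry: ~78% zero minutes (hence a zero 75th percentile), roughly 84%
of time in the lowest state (long resting bouts, mean ≈ 90 min, against
short 3–4 min activity bouts), a heavy right tail (state intensities 0.25 to
150 counts/min), and a night/day contrast (night raises the odds of zero,
lowers intensities most in the low states, and lengthens resting dwells).
Its per-state treatment coefficients rise monotonically from 0.02 to 0.09 on
the log scale.  Reported non-monotone per-state effect estimates, as real
analyses produce, are *population averages* and are not representable as a
single constrained subject — our truth uses a monotone approximation of that
magnitude range.  What the generator does **not** emulate: accelerometer
hardware artifacts (saturation, non-wear), behavioral autocorrelation beyond
the semi-Markov structure, covariate-by-treatment interactions in truth, or
real-animal realism beyond the calibration targets above.  Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not robustness to their violation.

## Reduced-scale experiment regimes

The shipped experiments (`actihsmm.experiments`) run at sizes a laptop
handles in minutes, chosen to preserve the asymptotic regime rather than the
raw scale of a real study (which would be `T ≈ 110,000` minutes for 58
subjects):

* single-subject recovery: `T ∈ {5,000; 20,000; 80,000}`, truth intensities
  1 and 5 — RMSE of the intensity intercepts shrinks as `T` grows;
* two-stage coverage: `n = 40` subjects × `T = 5,000` minutes × 100
  replicates (`n/T = 0.008`), two states with short dwells (`D_max = 6`),
  between-subject noise 0.1 on the monitored coefficient, optimizer `ftol =
  1e-8` for this experiment (the monitored state-2 coefficient is
  well-identified and its estimate is unchanged at the default tolerance);
* BIC selection: intensity ratio 10, `T = 20,000`, candidates {1, 2, 3},
  20 replicates;
* calibration: 10 subjects × 2 weeks of minutes from the 6-state truth.

## Numerical choices and degenerate inputs

* All dynamic programming in scaled probability or log domain; no
  probability-scale constants.  Scaled quantities stay O(1); a non-finite
  normalizer returns `-inf` and the optimizer treats the point as infeasible
  (penalty value, zero gradient).
* Duration grids whose CDF carries no mass on `{1..D_max}` (e.g. a tiny
  scale pushing everything below one minute) raise a "degenerate duration
  model" error rather than returning a renormalized artifact.
* `M = 1` is the degenerate single-state model: with self-transitions
  excluded no transition is possible, so the likelihood is the emission-only
  sum and decoding is a single censored segment.
* Degenerate data (all counts identical) fit with a warning and a flagged,
  boundary-safe result; series shorter than 50 minutes per free parameter
  warn.
* Exact zeros in emission probabilities cannot occur (ZIP/Poisson support is
  all of N), so per-minute normalization is always well defined.

## Known limitations

* The state-1 treatment coefficient and the zero-inflation treatment
  coefficient are weakly jointly identified at moderate `T` when the
  resting intensity is small — both mostly explain zeros.  Their estimates
  carry large standard errors at `T = 5,000`; population inference on them
  needs the long series a real study provides.
* Transition logits have no intercept (inherited from the model family), so
  baseline destination preferences cannot be expressed without covariates.
* The two-stage variance assumes subjects are independent and `n/T` small;
  with few subjects the HC0 sandwich is anti-conservative (no HC1/HC3
  correction is applied, by design).
* Label alignment across subjects relies entirely on the monotone-intensity
  constraint; if a subject truly lacks a high-activity state the rank
  alignment misassigns it.
* The Viterbi path is a single best segmentation; posterior state marginals
  are not exposed (the pipeline does not need them).
* Analysis-window selection (e.g. blinded periods only) happens at data
  preparation: the likelihood treats a series as one contiguous dwell
  process, so splicing non-contiguous windows together would misstate dwell
  lengths across the gap.  `blinded_window_mask` identifies the window; a
  future multi-segment likelihood would fit each contiguous chunk and sum.
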