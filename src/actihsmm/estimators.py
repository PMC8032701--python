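"""Subject-level maximum-likelihood estimation of the ZIP-HSMM.

``ZeroInflatedPoissonHSMM`` is a scikit-learn style estimator: ``fit`` finds
the subject's MLE by direct quasi-Newton maximization of the explicit-duration
forward likelihood over the unconstrained reparameterization (no EM), with
seeded multi-restart to guard against local optima; ``predict``/``decode``
run Viterbi; ``score`` evaluates the log-likelihood; ``sample`` simulates
from the fitted model.  Module-level functions (``fit_subject``,
``select_num_states``, ``model_quantile_check``) are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logit
from sklearn.base import BaseEstimator

from ._gradient import chain_to_unconstrained, loglik_and_score
from .config import ModelConfig
from .decoding import DecodedPath, viterbi_decode
from .likelihood import (build_tables, emission_log_table, forward_kernel,
                         forward_log_likelihood, series_cache)
from .parameters import (from_unconstrained, n_free_parameters,
                         n_unconstrained)
from .series import ActivitySeries

_PENALTY = 1e12


@dataclass
class SubjectFit:
    """MLE of one subject with diagnostics.

    ``bic = -2 loglik + n_params * ln T`` where ``n_params`` counts the free
    parameters of the optimized vector (the fixed initial distribution is
    excluded).
    """

    subject_id: str
    params_hat: SubjectParameters
    config: ModelConfig
    loglik: float
    n_params: int
    T: int
    bic: float
    converged: bool
    n_restarts_used: int
    gradient_norm: float


class ZeroInflatedPoissonHSMM(BaseEstimator):
    """Zero-inflated Poisson hidden semi-Markov model for one subject.

    Parameters
    ----------
    M : int
        Number of latent activity states.
    D_max : int
        Dwell-duration support cap in minutes.
    duration_family : str
        "weibull" (default) or "gamma" dwell base density.
    q, p_dim : int
        Treatment and environment covariate dimensions.
    n_restarts : int
        Seeded random restarts of the optimizer (first restart uses a
        data-driven initialization).
    tol : float
        Relative function tolerance of the quasi-Newton optimizer.  The
        default 1e-9 is deliberately tight: the log-likelihood magnitude
        grows with T, so a looser relative tolerance can halt while weakly
        identified coefficients (e.g. the state-1 treatment effect, which
        trades off against the zero-inflation logit) are still moving.
    max_iter : int
        Iteration cap per restart.
    random_state : int or None
        Seed controlling restart perturbations; fits are deterministic given
        (data, random_state).
    reestimate_delta : bool
        After fitting, re-estimate the initial distribution from the decoded
        path's state frequencies (the likelihood and BIC are then recomputed
        at the updated delta).  Default False: delta stays uniform and fixed.
    min_T_factor : int
        Advisory data-size floor: a warning is issued when
        ``T < min_T_factor * n_free_parameters``.
    """

    def __init__(self, M: int = 2, D_max: int = 360,
                 duration_family: str = "weibull", q: int = 1, p_dim: int = 2,
                 n_restarts: int = 5, tol: float = 1e-9, max_iter: int = 2000,
                 random_state=None, reestimate_delta: bool = False,
                 min_T_factor: int = 50):
        self.M = M
        self.D_max = D_max
        self.duration_family = duration_family
        self.q = q
        self.p_dim = p_dim
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.reestimate_delta = reestimate_delta
        self.min_T_factor = min_T_factor

    # -- configuration -----------------------------------------------------

    def model_config(self) -> ModelConfig:
        return ModelConfig(M=self.M, D_max=self.D_max,
                           duration_family=self.duration_family,
                           q=self.q, p_dim=self.p_dim)

    # -- fitting -----------------------------------------------------------

    def fit(self, series: ActivitySeries, y=None):
        config = self.model_config()
        series.check_config(config)
        T = series.T
        n_free = n_free_parameters(config)
        if T < self.min_T_factor * n_free:
            warnings.warn(
                f"T={T} is below the advisory minimum "
                f"{self.min_T_factor}*{n_free} for a reliable MLE")
        if np.all(series.y == series.y[0]):
            warnings.warn("degenerate data: all counts identical; "
                          "the fit will sit on a boundary")

        cache = series_cache(series)
        M = config.M
        n_delta = M - 1

        def objective(u_free: np.ndarray):
            # analytic score via the posterior-statistics forward-backward
            full = np.concatenate([np.zeros(n_delta), u_free])
            try:
                params = from_unconstrained(full, config)
                ll, grads = loglik_and_score(cache, params, config)
            except (ValueError, FloatingPointError):
                return _PENALTY, np.zeros_like(u_free)
            if grads is None or not np.isfinite(ll):
                return _PENALTY, np.zeros_like(u_free)
            g = chain_to_unconstrained(grads, u_free, config)
            if not np.all(np.isfinite(g)):
                return _PENALTY, np.zeros_like(u_free)
            return -ll, -g

        u0 = _initial_vector(series, config)
        best = None
        best_fun = np.inf
        n_used = 0
        any_success = False
        seed_base = 0 if self.random_state is None else int(self.random_state)
        for k in range(max(1, self.n_restarts)):
            if k == 0:
                uk = u0
            else:
                rng = np.random.default_rng([seed_base, k])
                uk = u0 + rng.normal(0.0, 0.3, size=u0.shape)
            # generous L-BFGS memory: the zero-inflation/state-1 trade-off
            # makes the surface ill-conditioned and extra curvature pairs
            # roughly halve the iteration count
            res = minimize(objective, uk, method="L-BFGS-B", jac=True,
                           options={"maxiter": self.max_iter,
                                    "ftol": self.tol, "gtol": 1e-5,
                                    "maxcor": 30})
            n_used = k + 1
            if res.fun < best_fun:
                best_fun = res.fun
                best = res
            if res.success and res.fun < _PENALTY / 2:
                any_success = True

        full = np.concatenate([np.zeros(n_delta), best.x])
        params = from_unconstrained(full, config)
        loglik = float(-best.fun)
        self.converged_ = bool(any_success and np.isfinite(loglik)
                               and best_fun < _PENALTY / 2)
        self.gradient_norm_ = float(np.max(np.abs(best.jac))) \
            if best.jac is not None else float("nan")

        if self.reestimate_delta and self.converged_:
            path = viterbi_decode(series, params, config, validate=False)
            freq = np.bincount(path.states, minlength=M + 1)[1:M + 1].astype(float)
            freq = np.maximum(freq, 1.0)  # keep delta interior
            params.delta = freq / freq.sum()
            loglik = forward_log_likelihood(series, params, config,
                                            validate=False)

        self.params_ = params
        self.log_likelihood_ = loglik
        self.n_parameters_ = n_free
        self.T_ = T
        self.bic_ = float(-2.0 * loglik + n_free * np.log(T))
        self.n_restarts_used_ = n_used
        return self

    # -- fitted-model queries ----------------------------------------------

    def score(self, series: ActivitySeries, y=None) -> float:
        return forward_log_likelihood(series, self.params_,
                                      self.model_config(), validate=False)

    def predict(self, series: ActivitySeries) -> np.ndarray:
        return self.decode(series).states

    def decode(self, series: ActivitySeries) -> DecodedPath:
        return viterbi_decode(series, self.params_, self.model_config(),
                              validate=False)

    def sample(self, x, z, random_state=None, subject_id="sim"):
        from .simulate import simulate_subject
        return simulate_subject(self.params_, x, z, self.model_config(),
                                seed=random_state, subject_id=subject_id)

    def to_subject_fit(self, subject_id: str | None = None) -> SubjectFit:
        return SubjectFit(
            subject_id=subject_id if subject_id is not None else "",
            params_hat=self.params_, config=self.model_config(),
            loglik=self.log_likelihood_, n_params=self.n_parameters_,
            T=self.T_, bic=self.bic_, converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            gradient_norm=self.gradient_norm_)


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _fast_loglik(cache, params, config) -> float:
    tables = build_tables(cache, params, config)
    ll_tab = emission_log_table(cache, tables)
    if config.M == 1:
        return float(ll_tab[cache.pair_idx, 0].sum())
    bmax = ll_tab.max(axis=1)
    bhat = np.exp(ll_tab - bmax[:, None])[cache.pair_idx]
    offset = float(bmax[cache.pair_idx].sum())
    core = forward_kernel(bhat, tables.r_tab, tables.s_tab, tables.q_tab,
                          cache.combo_idx, params.delta)
    return float(core + offset)


def _initial_vector(series: ActivitySeries, config: ModelConfig) -> np.ndarray:
    """Data-driven start excluding the delta block.

    Intensity intercepts come from quantile-group means of the positive
    counts; the zero-inflation intercept from the observed zero fraction;
    slopes start at zero, dwell base densities at shape 1 / scale 3.
    """
    M, q, p = config.M, config.q, config.p_dim
    y = series.y
    zero_frac = float(np.mean(y == 0))
    b00 = float(logit(np.clip(zero_frac, 0.05, 0.95)))
    pos = np.sort(y[y > 0]).astype(float)
    if pos.size >= M:
        groups = np.array_split(pos, M)
        lam = np.array([max(g.mean(), 1e-2) for g in groups])
    else:
        lam = np.exp(np.linspace(-1.0, 1.0, M))
    lam[0] = min(lam[0], max(0.5 * lam[0], 0.2))
    # enforce strictly increasing intensities before taking log increments
    for m in range(1, M):
        lam[m] = max(lam[m], lam[m - 1] * 1.5)
    b0 = np.log(lam)

    parts = [np.array([b00]), np.zeros(q), np.zeros(p), np.array([b0[0]])]
    if M > 1:
        parts.append(np.log(np.diff(b0)))
    # slope increments start slightly off zero: the squared-increment map has
    # zero gradient exactly at zero, which would freeze ties permanently
    parts.append(np.zeros(q))            # b1 first row
    if M > 1:
        parts.append(np.full((M - 1) * q, 0.1))
    parts.append(np.zeros(p))            # gamma first row
    if M > 1:
        parts.append(np.full((M - 1) * p, 0.1))
    parts.append(np.zeros(M))            # log shape = 0 -> shape 1
    parts.append(np.full(M, np.log(3.0)))  # log scale
    parts.append(np.zeros(M * q))        # c
    parts.append(np.zeros(M * p))        # eta
    if M >= 2:
        parts.append(np.zeros(M * (M - 2) * (q + p)))
    u0 = np.concatenate(parts)
    expected = n_unconstrained(config) - (M - 1)
    assert u0.shape[0] == expected, (u0.shape, expected)
    return u0


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def fit_subject(series: ActivitySeries, M: int, config: ModelConfig,
                seed: int | None = None, n_restarts: int = 5,
                tol: float = 1e-9, max_iter: int = 2000,
                reestimate_delta: bool = False) -> SubjectFit:
    """Maximum-likelihood fit of one subject's series at a given M."""
    est = ZeroInflatedPoissonHSMM(
        M=M, D_max=config.D_max, duration_family=config.duration_family,
        q=config.q, p_dim=config.p_dim, n_restarts=n_restarts, tol=tol,
        max_iter=max_iter, random_state=seed,
        reestimate_delta=reestimate_delta)
    est.fit(series)
    return est.to_subject_fit(series.subject_id)


def select_num_states(series: ActivitySeries, M_candidates, config: ModelConfig,
                      seed: int | None = None, **fit_kwargs):
    """Fit each candidate M and return (argmin-BIC M, per-candidate table).

    Ties break toward the smaller M; per-candidate failures are recorded in
    the table without aborting the sweep.
    """
    import pandas as pd

    candidates = sorted(set(int(m) for m in M_candidates))
    if not candidates:
        raise ValueError("M_candidates must be nonempty")
    rows = []
    fits = {}
    for M in candidates:
        try:
            fit = fit_subject(series, M, config, seed=seed, **fit_kwargs)
            fits[M] = fit
            rows.append({"M": M, "loglik": fit.loglik,
                         "n_params": fit.n_params, "bic": fit.bic,
                         "converged": fit.converged, "error": ""})
        except Exception as exc:  # propagate into the table, keep sweeping
            rows.append({"M": M, "loglik": np.nan, "n_params": np.nan,
                         "bic": np.nan, "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows).set_index("M")
    if table["bic"].isna().all():
        raise RuntimeError("every candidate fit failed:\n" + table.to_string())
    M_star = int(table["bic"].idxmin())  # first minimum; index sorted ascending
    return M_star, table, fits


def model_quantile_check(fit: SubjectFit, series: ActivitySeries,
                         quantile_grid, seed: int | None = None,
                         length_multiplier: int = 10) -> np.ndarray:
    """Model-vs-observed marginal count quantiles (a QQ check of fit).

    Simulates a long trajectory (``length_multiplier * T`` minutes) from the
    fitted model with the observed covariate schedule recycled, then pairs
    model quantiles with empirical data quantiles at the requested percents.

    Returns an array of shape (len(grid), 2): columns (model, observed).
    """
    from .simulate import simulate_subject

    if not fit.converged:
        raise ValueError("quantile check requires a converged fit")
    reps = max(1, int(length_multiplier))
    x = np.tile(series.x, (reps, 1))
    z = np.tile(series.z, (reps, 1))
    sim, _ = simulate_subject(fit.params_hat, x, z, fit.config, seed=seed,
                              subject_id=f"{fit.subject_id}-qq")
    grid = np.asarray(quantile_grid, dtype=float)
    model_q = np.percentile(sim.y, grid)
    obs_q = np.percentile(series.y, grid)
    return np.column_stack([model_q, obs_q])
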