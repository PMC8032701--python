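"""Exact likelihood of the ZIP-HSMM.

``forward_log_likelihood`` evaluates log P(Y^{1:T} | X, Z; theta) under the
generative model: initial state from delta, dwell lengths from the discretized
AFT duration model (covariates frozen at the minute the dwell begins), state
jumps from the multinomial-logit transition kernel (covariates at the minute
the jump occurs, i.e. the last minute of the old dwell), counts conditionally
independent given state and current covariates.  The final dwell is
right-censored through the duration survivor function.

``brute_force_log_likelihood`` is a deliberately naive enumeration over every
dwell segmentation, kept as an independent oracle for small T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from ._kernels import forward_kernel
from .config import ModelConfig
from .durations import _base_cdf, duration_pmf
from .emissions import emission_params, zip_log_pmf
from .parameters import SubjectParameters, validate_parameters
from .series import ActivitySeries
from .transitions import transition_row

_BRUTE_FORCE_T_LIMIT = 12


# ---------------------------------------------------------------------------
# per-series preprocessing (independent of the parameter value)
# ---------------------------------------------------------------------------

@dataclass
class SeriesCache:
    """Covariate-combination and (count, combo) pair indexing of one series.

    Emission probabilities depend on the minute only through the pair
    (y_t, covariate combination), and the duration/transition tables only
    through the combination — caching both index maps makes a likelihood
    evaluation cost O(T * M * D_max) multiply-adds plus tiny table builds.
    """

    combos_x: np.ndarray   # (C, q)
    combos_z: np.ndarray   # (C, p)
    combo_idx: np.ndarray  # (T,) int64
    pair_y: np.ndarray     # (P,) distinct (count, combo) pairs
    pair_combo: np.ndarray
    pair_idx: np.ndarray   # (T,) int64
    pair_lgam: np.ndarray  # (P,) log(y!)


def series_cache(series: ActivitySeries) -> SeriesCache:
    cache = getattr(series, "_hsmm_cache", None)
    if cache is not None:
        return cache
    q = series.q
    xz = np.hstack([series.x, series.z])
    combos, combo_idx = np.unique(xz, axis=0, return_inverse=True)
    combo_idx = combo_idx.astype(np.int64)
    keys = np.stack([combo_idx, series.y], axis=1)
    pairs, pair_idx = np.unique(keys, axis=0, return_inverse=True)
    cache = SeriesCache(
        combos_x=combos[:, :q].copy(),
        combos_z=combos[:, q:].copy(),
        combo_idx=combo_idx,
        pair_y=pairs[:, 1].astype(float),
        pair_combo=pairs[:, 0].astype(np.int64),
        pair_idx=pair_idx.astype(np.int64),
        pair_lgam=gammaln(pairs[:, 1].astype(float) + 1.0),
    )
    series._hsmm_cache = cache
    return cache


# ---------------------------------------------------------------------------
# parameter-dependent tables
# ---------------------------------------------------------------------------

@dataclass
class ModelTables:
    lam: np.ndarray       # (C, M) Poisson intensities
    p_zero: np.ndarray    # (C,)   state-1 zero-inflation weights
    r_tab: np.ndarray     # (C, M, V) dwell pmf
    s_tab: np.ndarray     # (C, M, V) dwell survivor
    q_tab: np.ndarray     # (C, M, M) transition probabilities


def build_tables(cache: SeriesCache, params: SubjectParameters,
                 config: ModelConfig) -> ModelTables:
    em, dur, tr = params.emission, params.duration, params.transition
    X, Z = cache.combos_x, cache.combos_z
    C = X.shape[0]
    M, V = config.M, config.D_max

    loglam = em.b0[None, :] + X @ em.b1.T + Z @ em.gamma.T
    with np.errstate(over="ignore"):  # inf intensities fail the finite check
        lam = np.exp(loglam)
    p_zero = expit(em.b00 + X @ em.b10 + Z @ em.gamma0)

    a = np.exp(X @ dur.c.T + Z @ dur.eta.T)          # (C, M)
    grid = a[:, :, None] * np.arange(1.0, V + 2.0)   # (C, M, V+1)
    F = _base_cdf(grid, config.duration_family,
                  dur.shape[None, :, None], dur.scale[None, :, None])
    total = F[:, :, -1] - F[:, :, 0]
    if not np.all(np.isfinite(total)) or np.any(total <= 0.0):
        raise ValueError(
            "degenerate duration model: no probability mass on the dwell "
            f"grid 1..{V} for some covariate combination"
        )
    r_tab = np.maximum(np.diff(F, axis=2), 0.0) / total[:, :, None]
    s_tab = np.maximum(F[:, :, -1:] - F[:, :, :-1], 0.0) / total[:, :, None]
    s_tab[:, :, 0] = 1.0

    if M >= 2:
        logits = np.einsum("mlq,cq->cml", tr.d_coef, X) \
            + np.einsum("mlp,cp->cml", tr.rho, Z)
        idx = np.arange(M)
        logits[:, idx, idx] = -np.inf
        logits -= logits.max(axis=2, keepdims=True)
        w = np.exp(logits)
        w[:, idx, idx] = 0.0
        q_tab = w / w.sum(axis=2, keepdims=True)
    else:
        q_tab = np.zeros((C, 1, 1))
    return ModelTables(lam=lam, p_zero=p_zero, r_tab=r_tab, s_tab=s_tab,
                       q_tab=q_tab)


def emission_log_table(cache: SeriesCache, tables: ModelTables) -> np.ndarray:
    """Log emission probabilities per distinct (count, combo) pair, (P, M)."""
    with np.errstate(divide="ignore"):
        loglam = np.log(tables.lam)
    lam_p = tables.lam[cache.pair_combo]
    ll = cache.pair_y[:, None] * loglam[cache.pair_combo] - lam_p \
        - cache.pair_lgam[:, None]
    pz = tables.p_zero[cache.pair_combo]
    with np.errstate(divide="ignore"):
        zero_part = np.where(cache.pair_y == 0.0, np.log(pz), -np.inf)
        ll[:, 0] = np.logaddexp(zero_part, np.log1p(-pz) + ll[:, 0])
    return ll


# ---------------------------------------------------------------------------
# public likelihood
# ---------------------------------------------------------------------------

def forward_log_likelihood(series: ActivitySeries, params: SubjectParameters,
                           config: ModelConfig, validate: bool = True) -> float:
    """Exact log-likelihood via the explicit-duration forward recursion."""
    if series.T == 0:
        raise ValueError("series is empty")
    series.check_config(config)
    if validate:
        violations = validate_parameters(params, config)
        if violations:
            raise ValueError(f"invalid parameters: {violations}")
    cache = series_cache(series)
    tables = build_tables(cache, params, config)
    ll_tab = emission_log_table(cache, tables)
    if config.M == 1:
        # single state: no transitions are possible once self-transitions are
        # excluded, so the dwell structure degenerates and the likelihood is
        # the emission-only sum
        return float(ll_tab[cache.pair_idx, 0].sum())
    bmax = ll_tab.max(axis=1)
    bhat = np.exp(ll_tab - bmax[:, None])[cache.pair_idx]
    offset = float(bmax[cache.pair_idx].sum())
    core = forward_kernel(bhat, tables.r_tab, tables.s_tab, tables.q_tab,
                          cache.combo_idx, params.delta)
    return float(core + offset)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_log_likelihood(series: ActivitySeries,
                               params: SubjectParameters,
                               config: ModelConfig) -> float:
    """Likelihood by exhaustive enumeration of dwell segmentations.

    Independent of the forward recursion: built from the elementary
    per-minute component functions and a recursive sweep over all
    compositions of 1..T into dwells with state labels.  Guarded to T <= 12.
    """
    T, M = series.T, config.M
    if T > _BRUTE_FORCE_T_LIMIT:
        raise ValueError(
            f"brute-force enumeration refused for T={T} > {_BRUTE_FORCE_T_LIMIT}"
        )
    loge = np.empty((T, M))
    for t in range(T):
        for m in range(1, M + 1):
            pz, lam = emission_params(m, series.x[t], series.z[t], params.emission)
            loge[t, m - 1] = zip_log_pmf(int(series.y[t]), pz, lam)
    if M == 1:
        return float(loge[:, 0].sum())

    logr = np.empty((T, M, config.D_max))
    logs = np.empty((T, M, config.D_max))
    with np.errstate(divide="ignore"):
        for t in range(T):
            for m in range(1, M + 1):
                pmf, surv = duration_pmf(m, series.x[t], series.z[t],
                                         params.duration, config)
                logr[t, m - 1] = np.log(pmf)
                logs[t, m - 1] = np.log(surv)
        logq = np.full((T, M, M), -np.inf)
        for t in range(T):
            for m in range(1, M + 1):
                logq[t, m - 1] = np.log(transition_row(m, series.x[t],
                                                       series.z[t],
                                                       params.transition))
        logdelta = np.log(params.delta)

    terms: list[float] = []

    def recurse(start: int, state: int, acc: float) -> None:
        # dwell of `state` (0-based) starting at 0-based minute `start`
        for v in range(1, min(config.D_max, T - start) + 1):
            emis = float(loge[start:start + v, state].sum())
            if start + v == T:
                terms.append(acc + logs[start, state, v - 1] + emis)
            else:
                step = acc + logr[start, state, v - 1] + emis
                if np.isfinite(step):
                    jump_t = start + v - 1  # transition occurs at this minute
                    for nxt in range(M):
                        if nxt != state:
                            recurse(start + v, nxt,
                                    step + logq[jump_t, state, nxt])

    for m0 in range(M):
        if np.isfinite(logdelta[m0]):
            recurse(0, m0, float(logdelta[m0]))
    if not terms:
        return -np.inf
    arr = np.asarray(terms)
    hi = arr.max()
    return float(hi + np.log(np.exp(arr - hi).sum()))
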