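"""Two-stage population inference on subject-level MLEs.

Stage one fits each subject's ZIP-HSMM; stage two regresses the subject-level
coefficient estimates on baseline covariates by ordinary least squares.  The
asymptotic covariance of the stacked estimator is the heteroskedasticity-
consistent sandwich

    (B'B/n)^(-1) (B' diag[e^2] B / n) (B'B/n)^(-1) / n,

with B the augmented design [1, W] replicated per coefficient (the Kronecker
block structure makes the computation separable per coefficient column).
Residuals absorb both genuine between-subject heterogeneity and first-stage
estimation noise, which is why no model for either is needed (valid in the
n/T -> 0 regime of high-frequency data).  Wald z tests against the standard
normal give the per-state treatment-effect table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .estimators import SubjectFit
from .transitions import reference_destination

FAMILIES = ("emission_treatment", "duration_treatment", "transition_treatment")


# ---------------------------------------------------------------------------
# stacking subject-level estimates
# ---------------------------------------------------------------------------

def _family_columns(family: str, config: ModelConfig) -> list[tuple]:
    M, q = config.M, config.q
    cols: list[tuple] = []
    if family == "emission_treatment":
        for j in range(q):
            cols.append(("zero_inflation", 0, j))
        for m in range(1, M + 1):
            for j in range(q):
                cols.append(("intensity", m, j))
    elif family == "duration_treatment":
        for m in range(1, M + 1):
            for j in range(q):
                cols.append(("duration", m, j))
    elif family == "transition_treatment":
        for m in range(1, M + 1):
            ref = reference_destination(m, M)
            for l in range(1, M + 1):
                if l == m or l == ref:
                    continue
                for j in range(q):
                    cols.append(("transition", (m, l), j))
    else:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return cols


def _extract_family(fit: SubjectFit, family: str) -> np.ndarray:
    em, dur, tr = (fit.params_hat.emission, fit.params_hat.duration,
                   fit.params_hat.transition)
    M = fit.config.M
    if family == "emission_treatment":
        return np.concatenate([em.b10, em.b1.ravel()])
    if family == "duration_treatment":
        return dur.c.ravel()
    if family == "transition_treatment":
        parts = []
        for m in range(1, M + 1):
            ref = reference_destination(m, M)
            for l in range(1, M + 1):
                if l == m or l == ref:
                    continue
                parts.append(tr.d_coef[m - 1, l - 1])
        return np.concatenate(parts) if parts else np.empty(0)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def stack_subject_estimates(fits, family: str):
    """Stack one coefficient family across subjects, aligned by state rank.

    States are comparable across subjects because the monotone-intensity
    constraint orders them within every fit; no post-hoc label matching is
    performed.

    Parameters
    ----------
    fits
        Mapping ``subject_id -> SubjectFit`` or iterable of SubjectFit.
    family
        "emission_treatment" (zero-inflation + per-state intensity treatment
        coefficients), "duration_treatment", or "transition_treatment".

    Returns
    -------
    (estimates, excluded)
        ``estimates`` is an (n_kept x K) DataFrame indexed by subject with a
        (component, state, covariate) column MultiIndex; ``excluded`` lists
        the ids of unconverged fits that were dropped.
    """
    if not isinstance(fits, dict):
        fits = {f.subject_id: f for f in fits}
    if not fits:
        raise ValueError("no subject fits supplied")
    configs = {(f.config.M, f.config.q) for f in fits.values()}
    if len(configs) > 1:
        raise ValueError(f"fits disagree on (M, q): {sorted(configs)}")
    config = next(iter(fits.values())).config
    cols = _family_columns(family, config)
    rows, excluded = {}, []
    for sid, fit in fits.items():
        if not fit.converged:
            excluded.append(sid)
            continue
        rows[sid] = _extract_family(fit, family)
    if not rows:
        raise ValueError("no converged fits to stack")
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if cols:
        frame.columns = pd.MultiIndex.from_tuples(
            cols, names=["component", "state", "covariate"])
    else:  # e.g. transitions at M=2: every destination is the reference
        frame = pd.DataFrame(index=frame.index,
                             columns=pd.MultiIndex.from_arrays(
                                 [[], [], []],
                                 names=["component", "state", "covariate"]))
    frame.index.name = "subject_id"
    return frame, excluded


# ---------------------------------------------------------------------------
# second-stage least squares with sandwich covariance
# ---------------------------------------------------------------------------

@dataclass
class PopulationEstimates:
    """OLS coefficients and sandwich covariances of one coefficient family.

    ``coef`` has one row per subject-level coefficient (K rows) and columns
    ``[intercept, <baseline covariates...>]``; ``cov[k]`` is the (d+1, d+1)
    sandwich covariance of row k; ``se`` the matching standard errors.  With
    centered baseline covariates the intercept estimates the population
    average of the subject-level coefficient.
    """

    family: str
    coef: pd.DataFrame
    cov: np.ndarray
    se: pd.DataFrame
    n_subjects: int
    centered: bool
    covariate_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "family": self.family,
            "columns": [str(c) for c in self.coef.columns],
            "rows": [str(r) for r in self.coef.index.tolist()],
            "coef": self.coef.to_numpy().tolist(),
            "cov": self.cov.tolist(),
            "se": self.se.to_numpy().tolist(),
            "n_subjects": self.n_subjects,
            "centered": self.centered,
            "covariate_names": list(self.covariate_names),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def sandwich_ols(y: np.ndarray, X: np.ndarray):
    """OLS with the HC0 sandwich covariance for one response column.

    Returns ``(beta, cov)`` with ``cov = (X'X)^-1 X' diag(e^2) X (X'X)^-1``.
    """
    XtX = X.T @ X
    A = np.linalg.inv(XtX)
    beta = A @ (X.T @ y)
    e = y - X @ beta
    meat = (X * (e ** 2)[:, None]).T @ X
    return beta, A @ meat @ A


def population_regress(estimates, baseline=None, center: bool = True,
                       scale: bool = False,
                       family: str = "emission_treatment") -> PopulationEstimates:
    """Second-stage least squares of subject estimates on baseline covariates.

    Parameters
    ----------
    estimates
        (n x K) DataFrame or array of subject-level coefficient estimates.
    baseline
        (n x d) DataFrame or array of baseline covariates W, row-aligned with
        ``estimates`` (matched on index when both are DataFrames); ``None``
        or zero columns gives the intercept-only regression.
    center, scale
        Center (default) and optionally standardize the baseline covariates
        so the intercept estimates the population-average effect; centering
        changes only the intercept, never the slopes or their covariances.

    Raises
    ------
    ValueError
        If n < d + 2 or the augmented design is rank deficient (the offending
        collinear columns are named).
    """
    if isinstance(estimates, pd.DataFrame):
        est = estimates.to_numpy(dtype=float)
        row_names = estimates.columns.tolist()
        subj_index = estimates.index
    else:
        est = np.atleast_2d(np.asarray(estimates, dtype=float))
        if est.shape[0] == 1 and est.size > 1 and est.shape[1] > 1 \
                and np.asarray(estimates).ndim == 1:
            est = est.T
        row_names = list(range(est.shape[1]))
        subj_index = None
    n, K = est.shape

    if baseline is None:
        W = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(baseline, pd.DataFrame):
        if subj_index is not None and baseline.index.size == n \
                and set(baseline.index) >= set(subj_index):
            baseline = baseline.loc[subj_index]
        W = baseline.to_numpy(dtype=float)
        names = [str(c) for c in baseline.columns]
    else:
        W = np.atleast_2d(np.asarray(baseline, dtype=float))
        if W.shape[0] != n:
            W = W.T
        names = [f"W{j}" for j in range(W.shape[1])]
    d = W.shape[1]
    if n < d + 2:
        raise ValueError(f"need at least d+2={d + 2} subjects, got n={n}")
    if center and d:
        W = W - W.mean(axis=0)
    if scale and d:
        sd = W.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [names[j] for j in np.where(sd == 0)[0]]
            raise ValueError(f"constant baseline columns cannot be scaled: {bad}")
        W = W / sd
    X = np.column_stack([np.ones(n), W])
    rank = np.linalg.matrix_rank(X)
    if rank < d + 1:
        bad = _collinear_columns(X, ["intercept"] + names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    coef = np.empty((K, d + 1))
    cov = np.empty((K, d + 1, d + 1))
    for k in range(K):
        coef[k], cov[k] = sandwich_ols(est[:, k], X)
    se = np.sqrt(np.maximum(np.einsum("kii->ki", cov), 0.0))
    columns = ["intercept"] + names
    index = pd.Index(row_names, tupleize_cols=False, name="coefficient")
    return PopulationEstimates(
        family=family,
        coef=pd.DataFrame(coef, index=index, columns=columns),
        cov=cov,
        se=pd.DataFrame(se, index=index, columns=columns),
        n_subjects=n, centered=center, covariate_names=names)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # name columns adding no rank on top of their predecessors
    bad, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            bad.append(names[j])
        else:
            kept = trial
    return bad


# ---------------------------------------------------------------------------
# Wald tests, effect sizes, report table
# ---------------------------------------------------------------------------

def wald_test(estimate: float, se: float):
    """z statistic and two-sided normal p-value of estimate / se."""
    if not se > 0:
        raise ValueError(f"standard error must be > 0, got {se}")
    z = estimate / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def effect_size_percent(coef: float, exponential: bool = False) -> float:
    """Percent effect size of a log-scale treatment coefficient.

    Default convention is 100 * coef (the small-coefficient linearization of
    the log link); ``exponential=True`` gives 100 * (e^coef - 1) instead —
    never substituted silently.
    """
    if exponential:
        return float(100.0 * np.expm1(coef))
    return float(100.0 * coef)


@dataclass
class EffectTable:
    """Per-state treatment-effect report (estimate, SE, z, p)."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    def to_text(self) -> str:
        cols = ["estimate", "se", "z", "p_value"]
        width = max(len(str(i)) for i in self.frame.index) + 2
        lines = ["Parameter".ljust(width)
                 + "".join(c.rjust(12) for c in cols)]
        for name, row in self.frame.iterrows():
            lines.append(str(name).ljust(width)
                         + "".join(f"{row[c]:12.4f}" for c in cols))
        return "\n".join(lines)

    def to_markdown(self) -> str:
        lines = ["| Parameter | Estimate | SE | z | p |",
                 "|---|---|---|---|---|"]
        for name, row in self.frame.iterrows():
            lines.append(
                f"| {name} | {row['estimate']:.4f} | {row['se']:.4f} "
                f"| {row['z']:.4f} | {row['p_value']:.4f} |")
        return "\n".join(lines)


def effect_table(pop: PopulationEstimates, config: ModelConfig,
                 treatment_index: int = 0) -> EffectTable:
    """Per-state treatment effects from the emission-family estimates.

    One row for the state-1 odds of zero and one per state's mean activity
    count, in increasing intensity order; the reported effect is the
    intercept of the (centered) second-stage regression, i.e. the population
    average of the subject-level treatment coefficient.
    """
    if pop.family != "emission_treatment":
        raise ValueError("effect_table expects emission_treatment estimates")
    rows = []
    for key, label in _effect_rows(config, treatment_index):
        estimate = float(pop.coef.loc[[key], "intercept"].iloc[0])
        se = float(pop.se.loc[[key], "intercept"].iloc[0])
        z, p = wald_test(estimate, se) if se > 0 else (np.nan, 1.0)
        rows.append({"parameter": label, "estimate": estimate, "se": se,
                     "z": z, "p_value": p})
    frame = pd.DataFrame(rows).set_index("parameter")
    return EffectTable(frame=frame)


def _effect_rows(config: ModelConfig, j: int):
    yield ("zero_inflation", 0, j), "State 1: odds of zero"
    for m in range(1, config.M + 1):
        yield ("intensity", m, j), f"State {m}: mean activity count"
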