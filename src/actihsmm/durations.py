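"""Dwell-time model: discretized accelerated failure time durations.

Each state ``m`` has a continuous base density ``f_m`` (Weibull by default,
gamma selectable) describing dwell length under the reference covariate
condition.  Covariates rescale time multiplicatively through the acceleration
factor ``a = exp(c_m'x + eta_m'z)``: the probability of an integer dwell of
``v`` minutes is the base-distribution mass of ``[a*v, a*(v+1))``, truncated
and renormalized to the finite support ``{1, ..., D_max}``.  Larger ``a``
therefore shortens dwells.  The AFT regression carries no intercept — it is
absorbed by the free scale parameter of the base density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc

from .config import ModelConfig


@dataclass
class DurationModel:
    """Per-state base-density parameters and AFT covariate coefficients.

    Attributes
    ----------
    shape, scale
        Strictly positive base-density parameters, length M.
    c
        Treatment coefficients of the acceleration factor, shape (M, q).
    eta
        Environment coefficients of the acceleration factor, shape (M, p).
    """

    shape: np.ndarray
    scale: np.ndarray
    c: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.shape = np.atleast_1d(np.asarray(self.shape, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        M = self.shape.shape[0]
        self.c = np.asarray(self.c, dtype=float).reshape(M, -1)
        self.eta = np.asarray(self.eta, dtype=float).reshape(M, -1)


def _base_cdf(u: np.ndarray, family: str, shape, scale) -> np.ndarray:
    # direct formulas (not scipy.stats frozen distributions): this sits in the
    # likelihood hot path and per-call distribution construction dominates
    u = np.asarray(u, dtype=float)
    if family == "weibull":
        with np.errstate(over="ignore"):  # saturated tail: F -> 1 exactly
            return -np.expm1(-np.power(u / scale, shape))
    if family == "gamma":
        return gammainc(shape, u / scale)
    raise ValueError(f"unknown duration family {family!r}")


def duration_pmf(m: int, x, z, dur: DurationModel, config: ModelConfig):
    """Dwell pmf and survivor function of state ``m`` at covariates (x, z).

    Returns
    -------
    (pmf, survivor)
        ``pmf[v-1]`` is ``P(dwell = v)`` for v in 1..D_max, summing to 1;
        ``survivor[v-1] = P(dwell >= v)`` is nonincreasing with
        ``survivor[0] = 1``.
    """
    M = dur.shape.shape[0]
    if not (1 <= m <= M):
        raise ValueError(f"state index m={m} out of range 1..{M}")
    shape = float(dur.shape[m - 1])
    scale = float(dur.scale[m - 1])
    if shape <= 0.0 or scale <= 0.0:
        raise ValueError(
            f"state {m}: duration shape and scale must be > 0 "
            f"(got shape={shape}, scale={scale})"
        )
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    a = float(np.exp(dur.c[m - 1] @ x + dur.eta[m - 1] @ z))
    return _pmf_from_accel(a, config.duration_family, shape, scale, config.D_max)


def _pmf_from_accel(a: float, family: str, shape: float, scale: float, D_max: int):
    """Truncated-renormalized discrete dwell pmf for acceleration factor a."""
    grid = a * np.arange(1.0, D_max + 2.0)
    F = _base_cdf(grid, family, shape, scale)
    mass = np.diff(F)
    total = F[-1] - F[0]
    if not np.isfinite(total) or total <= 0.0 or np.all(mass <= 0.0):
        raise ValueError(
            "degenerate duration model: no probability mass on the dwell grid "
            f"1..{D_max} (a={a}, shape={shape}, scale={scale})"
        )
    pmf = mass / total
    # survivor from the tail sum; enforce exact boundary conditions
    survivor = (F[-1] - F[:-1]) / total
    survivor[0] = 1.0
    return pmf, survivor


def duration_mean(pmf: np.ndarray) -> float:
    """Mean dwell length implied by a discrete dwell pmf."""
    v = np.arange(1, pmf.shape[0] + 1)
    return float(v @ pmf)
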