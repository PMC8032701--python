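"""Zero-inflated Poisson emission model.

In the lowest-intensity latent state (state 1) counts follow a mixture of a
point mass at zero (weight ``p_zero``, logit-linear in the covariates) and a
Poisson distribution; in states ``2..M`` counts are plain Poisson.  The log
intensity of every state is linear in treatment and environmental covariates,
and ordering constraints on the coefficients make the intensities strictly
increasing in the state index, which is what makes latent states comparable
across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln


def zip_log_pmf(y, p_zero, lam):
    """Log pmf of the zero-inflated Poisson distribution.

    ``P(Y = y) = p_zero * 1{y=0} + (1 - p_zero) * lam^y exp(-lam) / y!``

    Parameters
    ----------
    y
        Nonnegative integer count (scalar or array).
    p_zero
        Zero-inflation weight in [0, 1].
    lam
        Poisson intensity > 0 (``lam = 0`` is admitted only where ``y = 0``).

    Returns
    -------
    Log probability, broadcast over the inputs.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr != np.floor(y_arr)) or np.any(y_arr < 0):
        raise ValueError("y must consist of nonnegative integers")
    p_arr = np.asarray(p_zero, dtype=float)
    if np.any(p_arr < 0.0) or np.any(p_arr > 1.0):
        raise ValueError("p_zero must lie in [0, 1]")
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0.0):
        raise ValueError("lam must be nonnegative")
    if np.any((lam_arr == 0.0) & (np.asarray(y_arr, dtype=float) > 0)):
        raise ValueError("lam = 0 is only valid for y = 0")

    yf = np.asarray(y_arr, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pois = yf * np.log(np.where(lam_arr > 0, lam_arr, 1.0)) - lam_arr \
            - gammaln(yf + 1.0)
        log_pois = np.where((lam_arr == 0.0) & (yf == 0.0), 0.0, log_pois)
        # log[ p*1{y=0} + (1-p)*pois ] via a stable mixture combination
        with np.errstate(divide="ignore"):
            log_p = np.log(p_arr)
            log_1mp = np.log1p(-p_arr)
        a = np.where(yf == 0.0, log_p, -np.inf)
        b = log_1mp + log_pois
        out = np.logaddexp(a, b)
        # p_zero == 1: point mass at zero
        out = np.where(p_arr == 1.0, np.where(yf == 0.0, 0.0, -np.inf), out)
    if np.isscalar(y) and np.isscalar(p_zero) and np.isscalar(lam):
        return float(out)
    return out


@dataclass
class EmissionCoefficients:
    """Coefficients of the zero-inflation logit and the state log intensities.

    ``b00``, ``b10`` (length q) and ``gamma0`` (length p) parameterize the
    zero-inflation weight ``p_zero = logistic(b00 + b10'x + gamma0'z)``,
    applied in state 1 only.  ``b0`` (length M), ``b1`` (M x q) and ``gamma``
    (M x p) parameterize ``log lam_m = b0[m] + b1[m]'x + gamma[m]'z``.

    Ordering invariants (binary covariate designs): ``b0`` strictly increasing
    in m; every column of ``b1`` and ``gamma`` nondecreasing in m.  Together
    these force ``lam(m+1, x, z) > lam(m, x, z)`` for all covariate values.
    """

    b00: float
    b10: np.ndarray
    gamma0: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.b00 = float(self.b00)
        self.b10 = np.atleast_1d(np.asarray(self.b10, dtype=float))
        self.gamma0 = np.atleast_1d(np.asarray(self.gamma0, dtype=float))
        self.b0 = np.atleast_1d(np.asarray(self.b0, dtype=float))
        M = self.b0.shape[0]
        self.b1 = np.asarray(self.b1, dtype=float).reshape(M, -1)
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(M, -1)


def emission_params(m: int, x, z, coef: EmissionCoefficients):
    """Zero-inflation weight and Poisson intensity of state ``m`` at (x, z).

    Parameters
    ----------
    m
        1-based state index.
    x, z
        Treatment and environment covariate vectors.
    coef
        Emission coefficients.

    Returns
    -------
    (p_zero, lam)
        ``p_zero`` is the logistic zero-inflation weight for ``m = 1`` and
        exactly 0 for every other state; ``lam`` is the log-linear intensity.
    """
    M = coef.b0.shape[0]
    if not (1 <= m <= M):
        raise ValueError(f"state index m={m} out of range 1..{M}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if x.shape[0] != coef.b1.shape[1] or z.shape[0] != coef.gamma.shape[1]:
        raise ValueError(
            f"covariate dimensions ({x.shape[0]}, {z.shape[0]}) do not match "
            f"coefficients ({coef.b1.shape[1]}, {coef.gamma.shape[1]})"
        )
    lam = float(np.exp(coef.b0[m - 1] + coef.b1[m - 1] @ x + coef.gamma[m - 1] @ z))
    if m == 1:
        p_zero = float(expit(coef.b00 + coef.b10 @ x + coef.gamma0 @ z))
    else:
        p_zero = 0.0
    return p_zero, lam
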