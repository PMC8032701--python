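"""Covariate-dependent transition model between latent states.

Conditional on leaving state ``m``, the destination follows a multinomial
logit in the treatment and environment covariates.  Self-transitions are
structurally excluded — dwell lengths are owned by the duration model, so the
transition kernel is defined conditional on a state change.  For
identifiability the lowest-index allowed destination of each origin is the
reference category with coefficients fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TransitionCoefficients:
    """Multinomial-logit coefficients per (origin, destination) pair.

    ``d_coef[m, l]`` (length q) and ``rho[m, l]`` (length p) are the logits'
    covariate weights for a jump from origin ``m+1`` to destination ``l+1``
    (0-based array indexing).  The diagonal and each origin's reference
    destination (the lowest allowed index) hold zeros.
    """

    d_coef: np.ndarray  # (M, M, q)
    rho: np.ndarray     # (M, M, p)

    def __post_init__(self) -> None:
        self.d_coef = np.asarray(self.d_coef, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.d_coef.ndim != 3 or self.rho.ndim != 3:
            raise ValueError("d_coef and rho must have shape (M, M, dim)")
        if self.d_coef.shape[:2] != self.rho.shape[:2]:
            raise ValueError("d_coef and rho must agree on (M, M)")

    @property
    def M(self) -> int:
        return self.d_coef.shape[0]


def reference_destination(m: int, M: int) -> int:
    """1-based reference destination for origin ``m``: lowest allowed index."""
    return 2 if m == 1 else 1


def transition_row(m: int, x, z, coef: TransitionCoefficients) -> np.ndarray:
    """Probability vector over destinations 1..M for a jump out of state ``m``.

    Entry ``m`` is exactly 0; the remaining entries are a softmax of the
    covariate logits over the allowed destinations and sum to 1.

    Raises
    ------
    ValueError
        If ``M = 1`` (no transitions exist) or dimensions mismatch.
    """
    M = coef.M
    if M == 1:
        raise ValueError("transitions are undefined for a single-state model")
    if not (1 <= m <= M):
        raise ValueError(f"origin state m={m} out of range 1..{M}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if x.shape[0] != coef.d_coef.shape[2] or z.shape[0] != coef.rho.shape[2]:
        raise ValueError("covariate dimensions do not match transition coefficients")
    logits = coef.d_coef[m - 1] @ x + coef.rho[m - 1] @ z
    logits[m - 1] = -np.inf  # self-transition structurally excluded
    logits -= np.max(logits[np.isfinite(logits)])
    w = np.exp(logits)
    w[m - 1] = 0.0
    return w / w.sum()


def transition_matrix(x, z, coef: TransitionCoefficients) -> np.ndarray:
    """Stack of :func:`transition_row` over all origins, shape (M, M)."""
    return np.vstack([transition_row(m, x, z, coef) for m in range(1, coef.M + 1)])
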