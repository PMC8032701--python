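"""Numba kernels for the explicit-duration forward recursion and Viterbi.

The forward pass runs in the probability domain with per-minute rescaling
(emission probabilities are pre-normalized by their per-minute maximum and the
running normalizer is folded into the log-likelihood), so the hot loop is pure
multiply-add: complexity O(T * M * (M + D_max)) with no transcendental calls.
The Viterbi pass runs in the log domain, where max-sum needs additions only.

Table conventions shared by both kernels (C = number of distinct covariate
combinations observed in the series, V = D_max):

* ``r_tab[c, m, v-1]``  — dwell pmf P(dwell = v) in state m+1 under combo c
* ``s_tab[c, m, v-1]``  — survivor P(dwell >= v)
* ``q_tab[c, l, m]``    — transition probability l+1 -> m+1 (zero diagonal)
* ``combo[t]``          — covariate combo index of minute t+1
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def forward_kernel(bhat, r_tab, s_tab, q_tab, combo, delta):
    """Scaled forward log-likelihood, excluding the emission normalization
    offset (added by the caller).

    ``bhat[t, m]`` is the emission probability of minute t+1 in state m+1
    divided by that minute's maximum over states (so max_m bhat[t, m] = 1).
    The final dwell is right-censored through the survivor weights.
    """
    T, M = bhat.shape
    Vmax = r_tab.shape[2]
    A = np.empty((T, M))     # P(y_1:t, dwell ends at t) / prod N
    ent = np.empty((T, M))   # P(y_1:s-1, dwell of m starts at s) / prod N
    b2 = np.empty((T, M))    # bhat / N_t
    w = np.empty(M)
    for m in range(M):
        ent[0, m] = delta[m]
    loglik = 0.0
    for i in range(T):
        N = 0.0
        for m in range(M):
            vmax_t = min(i + 1, Vmax)
            prod = bhat[i, m]
            acc_a = 0.0
            acc_w = 0.0
            for v in range(1, vmax_t + 1):
                s = i - v + 1
                e = ent[s, m]
                cc = combo[s]
                acc_a += e * r_tab[cc, m, v - 1] * prod
                acc_w += e * s_tab[cc, m, v - 1] * prod
                if v < vmax_t:
                    prod *= b2[s - 1, m]
            A[i, m] = acc_a
            w[m] = acc_w
            N += acc_w
        if not (N > 0.0) or not np.isfinite(N):
            return -np.inf
        loglik += np.log(N)
        inv_n = 1.0 / N
        for m in range(M):
            A[i, m] *= inv_n
            b2[i, m] = bhat[i, m] * inv_n
        if i + 1 < T:
            cc = combo[i]
            for m in range(M):
                acc = 0.0
                for l in range(M):
                    if l != m:
                        acc += A[i, l] * q_tab[cc, l, m]
                ent[i + 1, m] = acc
    return loglik


@njit(cache=True)
def viterbi_kernel(loge, logr_tab, logs_tab, logq_tab, combo, logdelta):
    """Max-product analogue of the forward recursion.

    Returns ``(logprob, best_state, best_dwell, bp_v, bp_l)`` where the final
    (right-censored) segment is ``best_dwell`` minutes of ``best_state``
    (0-based), ``bp_v[t, m]`` is the optimal dwell length of a dwell of state
    m ending at t, and ``bp_l[s, m]`` the optimal predecessor state for a
    dwell of m starting at s.  Ties resolve to the lower state index, then the
    shorter dwell (strict improvement required while scanning in ascending
    order).
    """
    T, M = loge.shape
    Vmax = logr_tab.shape[2]
    # cumulative emission log-probs: ce[t, m] = sum_{u < t} loge[u, m]
    ce = np.zeros((T + 1, M))
    for i in range(T):
        for m in range(M):
            ce[i + 1, m] = ce[i, m] + loge[i, m]
    V = np.full((T, M), -np.inf)
    entv = np.full((T, M), -np.inf)
    bp_v = np.zeros((T, M), dtype=np.int64)
    bp_l = np.full((T, M), -1, dtype=np.int64)
    for m in range(M):
        entv[0, m] = logdelta[m]
    for i in range(T):
        for m in range(M):
            vmax_t = min(i + 1, Vmax)
            best = -np.inf
            bestv = 0
            for v in range(1, vmax_t + 1):
                s = i - v + 1
                val = entv[s, m] + logr_tab[combo[s], m, v - 1] \
                    + ce[i + 1, m] - ce[s, m]
                if val > best:
                    best = val
                    bestv = v
            V[i, m] = best
            bp_v[i, m] = bestv
        if i + 1 < T:
            cc = combo[i]
            for m in range(M):
                best = -np.inf
                bestl = -1
                for l in range(M):
                    if l != m:
                        val = V[i, l] + logq_tab[cc, l, m]
                        if val > best:
                            best = val
                            bestl = l
                entv[i + 1, m] = best
                bp_l[i + 1, m] = bestl
    # censored final dwell: survivor in place of the exact-duration pmf
    best = -np.inf
    best_m = 0
    best_v = 1
    vmax_t = min(T, Vmax)
    for m in range(M):
        for v in range(1, vmax_t + 1):
            s = T - v
            val = entv[s, m] + logs_tab[combo[s], m, v - 1] \
                + ce[T, m] - ce[s, m]
            if val > best:
                best = val
                best_m = m
                best_v = v
    return best, best_m, best_v, bp_v, bp_l
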