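"""Subject-level parameter set, constraint validation, and reparameterization.

The collection ``theta_i`` of one subject's parameters comprises the initial
state distribution, the emission coefficients, the dwell-time model, and the
transition coefficients.  Interpretability constraints order the latent states
by intensity: emission intercepts strictly increase with the state index and
treatment/environment slopes are nondecreasing, so state intensities are
monotone in ``m`` for every covariate value in a binary design.

For optimization the whole set maps to an unconstrained real vector:

* strictly increasing intercepts via a free first entry plus exp-mapped
  increments (always > 0);
* nondecreasing slopes via squared increments (>= 0, with equality exactly
  representable);
* probabilities via softmax, positive scales and shapes via exp.

``from_unconstrained`` is total — every real vector yields a parameter set
satisfying all invariants — and inverts ``to_unconstrained`` to high accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .durations import DurationModel
from .emissions import EmissionCoefficients
from .transitions import TransitionCoefficients, reference_destination

SCHEMA_VERSION = "1.0"

# exp arguments clipped to keep every mapped parameter finite
_EXP_CAP = 700.0


@dataclass
class SubjectParameters:
    """All subject-specific coefficients ``theta_i`` of the ZIP-HSMM."""

    delta: np.ndarray
    emission: EmissionCoefficients
    duration: DurationModel
    transition: TransitionCoefficients

    def __post_init__(self) -> None:
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))

    @property
    def M(self) -> int:
        return self.delta.shape[0]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_parameters(params: SubjectParameters, config: ModelConfig) -> list:
    """Check every invariant; return a list of ``(code, message)`` violations.

    Validation never raises — an empty list means the parameter set is valid.
    """
    v: list[tuple[str, str]] = []
    M, q, p = config.M, config.q, config.p_dim
    em, dur, tr = params.emission, params.duration, params.transition

    def dim(code, ok, msg):
        if not ok:
            v.append((code, msg))

    dim("dim_delta", params.delta.shape == (M,), f"delta shape {params.delta.shape} != ({M},)")
    dim("dim_emission", em.b0.shape == (M,) and em.b1.shape == (M, q)
        and em.gamma.shape == (M, p) and em.b10.shape == (q,)
        and em.gamma0.shape == (p,),
        "emission coefficient shapes inconsistent with config")
    dim("dim_duration", dur.shape.shape == (M,) and dur.scale.shape == (M,)
        and dur.c.shape == (M, q) and dur.eta.shape == (M, p),
        "duration coefficient shapes inconsistent with config")
    dim("dim_transition", tr.d_coef.shape == (M, M, q) and tr.rho.shape == (M, M, p),
        "transition coefficient shapes inconsistent with config")
    if v:
        return v  # dimension errors make the remaining checks meaningless

    if np.any(params.delta < 0) or abs(params.delta.sum() - 1.0) > 1e-8:
        v.append(("delta_simplex",
                  f"delta must be a probability vector, got {params.delta}"))
    if M > 1:
        if not np.all(np.diff(em.b0) > 0):
            v.append(("b0_ordering", "emission intercepts b0 must be strictly increasing"))
        if not np.all(np.diff(em.b1, axis=0) >= 0):
            v.append(("b1_ordering", "emission treatment slopes b1 must be nondecreasing in m"))
        if not np.all(np.diff(em.gamma, axis=0) >= 0):
            v.append(("gamma_ordering", "emission environment slopes gamma must be nondecreasing in m"))
    if np.any(dur.shape <= 0) or np.any(dur.scale <= 0):
        v.append(("duration_positivity", "duration shape and scale must be strictly positive"))
    if not np.all(np.isfinite(em.b0)) or not np.all(np.isfinite(em.b1)) \
            or not np.all(np.isfinite(em.gamma)) or not np.isfinite(em.b00):
        v.append(("finite", "emission coefficients must be finite"))
    for m in range(M):
        if np.any(tr.d_coef[m, m] != 0) or np.any(tr.rho[m, m] != 0):
            v.append(("self_transition",
                      f"origin {m + 1}: diagonal transition coefficients must be zero"))
        if M >= 2:
            ref = reference_destination(m + 1, M) - 1
            if np.any(tr.d_coef[m, ref] != 0) or np.any(tr.rho[m, ref] != 0):
                v.append(("transition_reference",
                          f"origin {m + 1}: reference destination {ref + 1} "
                          "must have zero coefficients"))
    return v


# ---------------------------------------------------------------------------
# unconstrained reparameterization
# ---------------------------------------------------------------------------

def n_unconstrained(config: ModelConfig) -> int:
    """Length of the full unconstrained vector (including the delta block)."""
    M, q, p = config.M, config.q, config.p_dim
    n = (M - 1)                    # delta (softmax, reference = state 1)
    n += 1 + q + p                 # zero-inflation logit
    n += M + M * q + M * p         # emission intercepts + slopes
    n += 2 * M + M * q + M * p     # duration shape, scale, AFT coefficients
    if M >= 2:
        n += M * (M - 2) * (q + p)  # transition logits (reference fixed at 0)
    return n


def n_free_parameters(config: ModelConfig) -> int:
    """Free parameters counted by BIC: the optimized vector, excluding delta.

    The initial distribution is held fixed (uniform) during optimization, so
    its M-1 softmax coordinates are not counted.
    """
    return n_unconstrained(config) - (config.M - 1)


def _cap_exp(u):
    return np.exp(np.minimum(u, _EXP_CAP))


def _strict_increase(first: float, inc_u: np.ndarray) -> np.ndarray:
    """first, then cumulative exp-mapped increments; strictness enforced."""
    out = np.empty(inc_u.shape[0] + 1)
    out[0] = first
    for i, u in enumerate(inc_u):
        nxt = out[i] + _cap_exp(u)
        if nxt <= out[i]:  # increment below float resolution
            nxt = np.nextafter(out[i], np.inf)
        out[i + 1] = nxt
    return out


def from_unconstrained(vec: np.ndarray, config: ModelConfig) -> SubjectParameters:
    """Map any real vector to a valid :class:`SubjectParameters`."""
    vec = np.asarray(vec, dtype=float)
    n_expected = n_unconstrained(config)
    if vec.shape != (n_expected,):
        raise ValueError(f"expected vector of length {n_expected}, got shape {vec.shape}")
    M, q, p = config.M, config.q, config.p_dim
    pos = 0

    def take(k):
        nonlocal pos
        out = vec[pos:pos + k]
        pos += k
        return out

    logits = np.concatenate([[0.0], take(M - 1)])
    w = np.exp(logits - logits.max())
    delta = w / w.sum()

    b00 = float(take(1)[0])
    b10 = take(q).copy()
    gamma0 = take(p).copy()
    b0 = _strict_increase(float(take(1)[0]), take(M - 1))
    b1 = np.cumsum(np.vstack([take(q), take((M - 1) * q).reshape(M - 1, q) ** 2]), axis=0) \
        if M > 1 else take(q).reshape(1, q)
    gamma = np.cumsum(np.vstack([take(p), take((M - 1) * p).reshape(M - 1, p) ** 2]), axis=0) \
        if M > 1 else take(p).reshape(1, p)
    emission = EmissionCoefficients(b00=b00, b10=b10, gamma0=gamma0,
                                    b0=b0, b1=b1, gamma=gamma)

    shape = _cap_exp(take(M))
    scale = _cap_exp(take(M))
    c = take(M * q).reshape(M, q).copy()
    eta = take(M * p).reshape(M, p).copy()
    duration = DurationModel(shape=shape, scale=scale, c=c, eta=eta)

    d_coef = np.zeros((M, M, q))
    rho = np.zeros((M, M, p))
    if M >= 2:
        for m in range(1, M + 1):
            ref = reference_destination(m, M)
            for l in range(1, M + 1):
                if l == m or l == ref:
                    continue
                d_coef[m - 1, l - 1] = take(q)
                rho[m - 1, l - 1] = take(p)
    transition = TransitionCoefficients(d_coef=d_coef, rho=rho)

    assert pos == n_expected
    return SubjectParameters(delta=delta, emission=emission,
                             duration=duration, transition=transition)


def to_unconstrained(params: SubjectParameters) -> np.ndarray:
    """Inverse of :func:`from_unconstrained` (round trip within 1e-10)."""
    em, dur, tr = params.emission, params.duration, params.transition
    M = params.M
    q = em.b1.shape[1]
    p = em.gamma.shape[1]
    parts = []
    with np.errstate(divide="ignore"):
        parts.append(np.log(params.delta[1:] / params.delta[0]))
        parts.append([em.b00])
        parts.append(em.b10)
        parts.append(em.gamma0)
        parts.append([em.b0[0]])
        parts.append(np.log(np.diff(em.b0)))
        parts.append(em.b1[0])
        if M > 1:
            parts.append(np.sqrt(np.diff(em.b1, axis=0)).ravel())
        parts.append(em.gamma[0])
        if M > 1:
            parts.append(np.sqrt(np.diff(em.gamma, axis=0)).ravel())
        parts.append(np.log(dur.shape))
        parts.append(np.log(dur.scale))
        parts.append(dur.c.ravel())
        parts.append(dur.eta.ravel())
        if M >= 2:
            for m in range(1, M + 1):
                ref = reference_destination(m, M)
                for l in range(1, M + 1):
                    if l == m or l == ref:
                        continue
                    parts.append(tr.d_coef[m - 1, l - 1])
                    parts.append(tr.rho[m - 1, l - 1])
    return np.concatenate([np.atleast_1d(np.asarray(a, dtype=float)) for a in parts])


def default_parameters(config: ModelConfig) -> SubjectParameters:
    """Valid parameter set at the origin of the unconstrained space."""
    return from_unconstrained(np.zeros(n_unconstrained(config)), config)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def params_to_dict(params: SubjectParameters, config: ModelConfig) -> dict:
    em, dur, tr = params.emission, params.duration, params.transition
    return {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "delta": params.delta.tolist(),
        "emission": {
            "b00": em.b00, "b10": em.b10.tolist(), "gamma0": em.gamma0.tolist(),
            "b0": em.b0.tolist(), "b1": em.b1.tolist(), "gamma": em.gamma.tolist(),
        },
        "duration": {
            "shape": dur.shape.tolist(), "scale": dur.scale.tolist(),
            "c": dur.c.tolist(), "eta": dur.eta.tolist(),
        },
        "transition": {
            "d_coef": tr.d_coef.tolist(), "rho": tr.rho.tolist(),
        },
    }


_KNOWN_KEYS = {"schema_version", "config", "delta", "emission", "duration", "transition"}


def params_from_dict(data: dict) -> tuple[SubjectParameters, ModelConfig]:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"parameter schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION!r})"
        )
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown fields in parameter JSON: {sorted(unknown)}")
    config = ModelConfig.from_dict(data["config"])
    em = data["emission"]
    dur = data["duration"]
    tr = data["transition"]
    params = SubjectParameters(
        delta=np.asarray(data["delta"], dtype=float),
        emission=EmissionCoefficients(
            b00=em["b00"], b10=em["b10"], gamma0=em["gamma0"],
            b0=em["b0"], b1=em["b1"], gamma=em["gamma"]),
        duration=DurationModel(shape=dur["shape"], scale=dur["scale"],
                               c=dur["c"], eta=dur["eta"]),
        transition=TransitionCoefficients(
            d_coef=np.asarray(tr["d_coef"], dtype=float),
            rho=np.asarray(tr["rho"], dtype=float)),
    )
    violations = validate_parameters(params, config)
    if violations:
        raise ValueError(f"loaded parameters violate invariants: {violations}")
    return params, config


def save_params(path, params: SubjectParameters, config: ModelConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params_to_dict(params, config), fh, indent=1)


def load_params(path) -> tuple[SubjectParameters, ModelConfig]:
    with open(path, encoding="utf-8") as fh:
        return params_from_dict(json.load(fh))
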