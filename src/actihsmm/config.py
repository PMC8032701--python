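"""Model configuration for the zero-inflated Poisson hidden semi-Markov model.

The model describes minute-epoch activity counts through ``M`` latent activity
states ordered by mean intensity.  Dwell times have an explicit (finite-support)
duration distribution per state, discretized from an accelerated failure time
model; transitions between distinct states follow a multinomial logit in the
covariates; counts are zero-inflated Poisson in the lowest state and plain
Poisson above it.
"""

from __future__ import annotations

from dataclasses import dataclass

DURATION_FAMILIES = ("weibull", "gamma")


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions and structural settings of a ZIP-HSMM.

    Parameters
    ----------
    M
        Number of latent activity states (>= 1).
    D_max
        Maximum dwell duration in minutes.  Dwell distributions are truncated
        and renormalized to ``{1, ..., D_max}``, giving the duration law finite
        support.  The default of 360 minutes comfortably exceeds plausible
        single-activity bouts at minute resolution while keeping the forward
        recursion affordable.
    duration_family
        Base density family of the dwell model, ``"weibull"`` (default) or
        ``"gamma"``.  Both are closed under the accelerated-failure-time
        rescaling used for covariate effects.
    q
        Dimension of the treatment covariate vector ``x`` (binary indicator in
        the motivating crossover study).
    p_dim
        Dimension of the environmental covariate vector ``z`` (night and
        weekend indicators in the motivating study).
    d
        Dimension of the per-subject baseline covariate vector ``W``.
    """

    M: int
    D_max: int = 360
    duration_family: str = "weibull"
    q: int = 1
    p_dim: int = 2
    d: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.M, (int,)) and self.M >= 1):
            raise ValueError(f"M must be an integer >= 1, got {self.M!r}")
        if not (isinstance(self.D_max, (int,)) and self.D_max >= 1):
            raise ValueError(f"D_max must be an integer >= 1, got {self.D_max!r}")
        if self.duration_family not in DURATION_FAMILIES:
            raise ValueError(
                f"duration_family must be one of {DURATION_FAMILIES}, "
                f"got {self.duration_family!r}"
            )
        for name in ("q", "p_dim", "d"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "D_max": self.D_max,
            "duration_family": self.duration_family,
            "q": self.q,
            "p_dim": self.p_dim,
            "d": self.d,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        return cls(
            M=int(data["M"]),
            D_max=int(data["D_max"]),
            duration_family=str(data["duration_family"]),
            q=int(data["q"]),
            p_dim=int(data["p_dim"]),
            d=int(data["d"]),
        )
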