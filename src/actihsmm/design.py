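"""Crossover study design and per-minute covariate schedules.

The default design mirrors an 11-week randomized crossover at 1-minute
epochs: a 2-week open-label baseline, a 3-week blinded treatment period
(weeks 3-5), a 3-week blinded washout (weeks 6-8), and a second 3-week
blinded period (weeks 9-11) with treatments switched.  Sequence "A" receives
active treatment first, sequence "B" second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEQUENCES = ("A", "B")


@dataclass(frozen=True)
class StudyDesign:
    """Crossover schedule specification driving the simulator.

    Night covers minute-of-day >= ``night_start_minute`` or
    < ``night_end_minute`` (default 18:00-06:00; the clock wraps midnight).
    Day 0 is a Monday, so weekends are days 5 and 6 of each week.
    """

    n_subjects: int = 10
    weeks_baseline: int = 2
    weeks_period1: int = 3
    weeks_washout: int = 3
    weeks_period2: int = 3
    minutes_per_day: int = 1440
    night_start_minute: int = 1080
    night_end_minute: int = 360
    analysis_window: str = "all"  # "all" or "blinded"

    def __post_init__(self) -> None:
        if self.analysis_window not in ("all", "blinded"):
            raise ValueError("analysis_window must be 'all' or 'blinded'")
        for f in ("n_subjects", "weeks_baseline", "weeks_period1",
                  "weeks_washout", "weeks_period2", "minutes_per_day"):
            if getattr(self, f) < 0 or (f in ("n_subjects", "minutes_per_day")
                                        and getattr(self, f) < 1):
                raise ValueError(f"{f} must be positive")

    @property
    def total_weeks(self) -> int:
        return (self.weeks_baseline + self.weeks_period1
                + self.weeks_washout + self.weeks_period2)

    @property
    def total_days(self) -> int:
        return 7 * self.total_weeks

    @property
    def total_minutes(self) -> int:
        return self.total_days * self.minutes_per_day

    def period_days(self):
        """(start_day, end_day) half-open per phase in design order."""
        b = 7 * self.weeks_baseline
        p1 = b + 7 * self.weeks_period1
        w = p1 + 7 * self.weeks_washout
        p2 = w + 7 * self.weeks_period2
        return {"baseline": (0, b), "period1": (b, p1),
                "washout": (p1, w), "period2": (w, p2)}


def make_crossover_schedule(design: StudyDesign, sequence: str):
    """Deterministic per-minute covariates (x, z) for one treatment sequence.

    Returns
    -------
    (x, z)
        ``x``: (T, 1) treatment indicator, 1 exactly during the active-drug
        phase of the given sequence; ``z``: (T, 2) columns (night, weekend).
    """
    if sequence not in SEQUENCES:
        raise ValueError(f"sequence must be one of {SEQUENCES}, got {sequence!r}")
    T = design.total_minutes
    minute = np.arange(T)
    day = minute // design.minutes_per_day
    minute_of_day = minute % design.minutes_per_day

    periods = design.period_days()
    active = periods["period1"] if sequence == "A" else periods["period2"]
    x = ((day >= active[0]) & (day < active[1])).astype(float)[:, None]

    night = ((minute_of_day >= design.night_start_minute)
             | (minute_of_day < design.night_end_minute)).astype(float)
    weekend = ((day % 7) >= 5).astype(float)
    z = np.column_stack([night, weekend])
    return x, z


def blinded_window_mask(design: StudyDesign) -> np.ndarray:
    """Boolean per-minute mask covering the two blinded treatment periods."""
    T = design.total_minutes
    day = np.arange(T) // design.minutes_per_day
    periods = design.period_days()
    (a0, a1), (b0, b1) = periods["period1"], periods["period2"]
    return ((day >= a0) & (day < a1)) | ((day >= b0) & (day < b1))


def treatment_condition_labels(x: np.ndarray, mask: np.ndarray | None = None):
    """Per-minute labels "treatment"/"placebo" from the x indicator."""
    labels = np.where(x[:, 0] > 0, "treatment", "placebo")
    if mask is not None:
        labels = np.where(mask, labels, "excluded")
    return labels
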