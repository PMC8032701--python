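"""Viterbi decoding of the explicit-duration model and occupancy summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import viterbi_kernel
from .config import ModelConfig
from .likelihood import build_tables, emission_log_table, series_cache
from .parameters import SubjectParameters, validate_parameters
from .series import ActivitySeries


@dataclass
class DecodedPath:
    """Most probable dwell/state segmentation of one subject's series.

    ``states`` holds the 1-based decoded state per minute; ``segments`` is a
    list of ``(state, start_t, duration)`` with 1-based start minutes that
    partitions 1..T; ``log_prob`` is the joint log-probability of the decoded
    path and the data; the final segment is right-censored at T and flagged.
    """

    subject_id: str
    states: np.ndarray
    segments: list = field(default_factory=list)
    log_prob: float = float("nan")
    final_censored: bool = True

    @property
    def T(self) -> int:
        return self.states.shape[0]

    def segments_frame(self) -> pd.DataFrame:
        """Segment table with half-open [start, end) minute intervals."""
        rows = [
            {"subject_id": self.subject_id, "start": s, "end": s + v, "state": m}
            for (m, s, v) in self.segments
        ]
        return pd.DataFrame(rows, columns=["subject_id", "start", "end", "state"])


def viterbi_decode(series: ActivitySeries, params: SubjectParameters,
                   config: ModelConfig, validate: bool = True) -> DecodedPath:
    """Jointly most probable dwell segmentation under the fitted model.

    Ties break toward the lower state index, then the shorter dwell.
    """
    series.check_config(config)
    if validate:
        violations = validate_parameters(params, config)
        if violations:
            raise ValueError(f"invalid parameters: {violations}")
    T, M = series.T, config.M
    if M == 1:
        states = np.ones(T, dtype=np.int64)
        loge = _emission_logs(series, params, config)
        return DecodedPath(subject_id=series.subject_id, states=states,
                           segments=[(1, 1, T)],
                           log_prob=float(loge[:, 0].sum()),
                           final_censored=True)
    cache = series_cache(series)
    tables = build_tables(cache, params, config)
    loge = emission_log_table(cache, tables)[cache.pair_idx]
    with np.errstate(divide="ignore"):
        logr = np.log(tables.r_tab)
        logs = np.log(tables.s_tab)
        logq = np.where(tables.q_tab > 0, np.log(
            np.where(tables.q_tab > 0, tables.q_tab, 1.0)), -np.inf)
        logdelta = np.log(params.delta)
    logprob, best_m, best_v, bp_v, bp_l = viterbi_kernel(
        loge, logr, logs, logq, cache.combo_idx, logdelta)

    # backtrace: final censored segment, then exact dwells
    segments: list[tuple[int, int, int]] = []
    m, v, end = int(best_m), int(best_v), T  # end is 1-based inclusive
    while True:
        start = end - v + 1
        segments.append((m + 1, start, v))
        if start == 1:
            break
        prev = int(bp_l[start - 1, m])  # predecessor of dwell starting at `start`
        m = prev
        end = start - 1
        v = int(bp_v[end - 1, m])
    segments.reverse()
    states = np.empty(T, dtype=np.int64)
    for (state, start, dur) in segments:
        states[start - 1:start - 1 + dur] = state
    return DecodedPath(subject_id=series.subject_id, states=states,
                       segments=segments, log_prob=float(logprob),
                       final_censored=True)


def _emission_logs(series, params, config):
    cache = series_cache(series)
    tables = build_tables(cache, params, config)
    return emission_log_table(cache, tables)[cache.pair_idx]


def state_occupancy(paths, condition_labels, M: int | None = None,
                    conditions=None) -> pd.DataFrame:
    """Mean percent time per state per condition, averaged over subjects.

    Parameters
    ----------
    paths
        Mapping ``subject_id -> DecodedPath`` (or an iterable of paths).
    condition_labels
        Mapping ``subject_id -> array of per-minute condition labels`` aligned
        with each subject's decoded minutes (e.g. "meloxicam"/"placebo").
    M
        Number of states; inferred from the decoded paths when omitted.
    conditions
        Conditions to tabulate, defaulting to those present in the labels; a
        requested condition with no minutes anywhere is dropped with a
        warning.

    Returns
    -------
    DataFrame indexed by state 1..M with one column per condition; each column
    sums to 100 (up to rounding).  Conditions with no minutes for a subject
    are skipped for that subject; conditions empty everywhere are dropped with
    a warning.
    """
    if not isinstance(paths, dict):
        paths = {p.subject_id: p for p in paths}
    if M is None:
        M = int(max(p.states.max() for p in paths.values()))
    all_conditions = list(conditions) if conditions is not None else []
    for sid, path in paths.items():
        labels = np.asarray(condition_labels[sid])
        if labels.shape[0] != path.T:
            raise ValueError(
                f"subject {sid}: {labels.shape[0]} labels for {path.T} minutes")
        if conditions is None:
            for c in pd.unique(labels):
                if c not in all_conditions:
                    all_conditions.append(c)
    table = {}
    for cond in all_conditions:
        per_subject = []
        for sid, path in paths.items():
            mask = np.asarray(condition_labels[sid]) == cond
            n = int(mask.sum())
            if n == 0:
                continue
            counts = np.bincount(path.states[mask], minlength=M + 1)[1:M + 1]
            per_subject.append(100.0 * counts / n)
        if not per_subject:
            warnings.warn(f"condition {cond!r} has no minutes; excluded")
            continue
        table[cond] = np.mean(per_subject, axis=0)
    return pd.DataFrame(table, index=pd.Index(range(1, M + 1), name="state"))
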