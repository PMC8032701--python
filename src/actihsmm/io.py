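"""Readers and writers for the package's plain-text data formats.

Activity data travel as long-format CSV (one row per subject-minute, columns
``subject_id, t, y, x_*, z_*``; comma-separated, UTF-8, "." decimal, header
mandatory).  Parameters, fits and population estimates serialize to
schema-versioned JSON; decoded paths export as per-minute CSV and as a
segment table with half-open [start, end) minute intervals.
"""

from __future__ import annotations

import json
import re

import numpy as np
import pandas as pd

from .estimators import SubjectFit
from .parameters import params_from_dict, params_to_dict
from .series import ActivitySeries

_REQUIRED = ("subject_id", "t", "y")


def _covariate_columns(columns, prefix: str) -> list[str]:
    pat = re.compile(rf"^{prefix}_(\d+)$")
    found = [(int(m.group(1)), c) for c in columns if (m := pat.match(c))]
    return [c for _, c in sorted(found)]


def read_activity_table(path) -> list[ActivitySeries]:
    """Read a long-format activity CSV into per-subject series.

    Validates presence of the required columns, nonnegative integer counts
    (errors cite 1-based data row numbers), and per-subject minute indices
    contiguous from 1 — gaps are an error, never silently imputed.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"activity table missing required column(s): {missing}")
    x_cols = _covariate_columns(frame.columns, "x")
    z_cols = _covariate_columns(frame.columns, "z")

    errors = []
    y_num = pd.to_numeric(frame["y"], errors="coerce")
    bad = frame.index[y_num.isna() | (y_num < 0) | (y_num != np.floor(y_num))]
    for i in bad[:20]:
        errors.append(f"row {i + 1}: y={frame['y'].iloc[i]!r} is not a "
                      "nonnegative integer")
    if errors:
        raise ValueError("malformed activity table:\n" + "\n".join(errors))

    series_list = []
    for sid, grp in frame.groupby("subject_id", sort=True):
        grp = grp.sort_values("t")
        t = grp["t"].to_numpy()
        expected = np.arange(1, len(t) + 1)
        if not np.array_equal(t, expected):
            gap = int(expected[np.argmax(t != expected)])
            raise ValueError(
                f"subject {sid}: minute index not contiguous from 1 "
                f"(first problem at t={gap}); gaps are not imputed")
        T = len(t)
        x = grp[x_cols].to_numpy(dtype=float) if x_cols else np.zeros((T, 0))
        z = grp[z_cols].to_numpy(dtype=float) if z_cols else np.zeros((T, 0))
        series_list.append(ActivitySeries(
            subject_id=str(sid), y=grp["y"].to_numpy(dtype=np.int64), x=x, z=z))
    return series_list


def write_activity_table(series_list, path) -> None:
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_baseline_table(baseline: pd.DataFrame, path) -> None:
    baseline.to_csv(path, index=True)


def read_baseline_table(path) -> pd.DataFrame:
    from .series import validate_baseline_table
    return validate_baseline_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# fit JSON
# ---------------------------------------------------------------------------

def fit_to_dict(fit: SubjectFit) -> dict:
    payload = params_to_dict(fit.params_hat, fit.config)
    payload.update({
        "subject_id": fit.subject_id,
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "T": fit.T,
        "bic": fit.bic,
        "converged": fit.converged,
        "n_restarts_used": fit.n_restarts_used,
        "gradient_norm": fit.gradient_norm,
    })
    return payload


def fit_from_dict(data: dict) -> SubjectFit:
    params, config = params_from_dict(
        {k: data[k] for k in
         ("schema_version", "config", "delta", "emission", "duration",
          "transition")})
    return SubjectFit(
        subject_id=str(data["subject_id"]), params_hat=params, config=config,
        loglik=float(data["loglik"]), n_params=int(data["n_params"]),
        T=int(data["T"]), bic=float(data["bic"]),
        converged=bool(data["converged"]),
        n_restarts_used=int(data["n_restarts_used"]),
        gradient_norm=float(data["gradient_norm"]))


def save_fit(path, fit: SubjectFit) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fit_to_dict(fit), fh, indent=1)


def load_fit(path) -> SubjectFit:
    with open(path, encoding="utf-8") as fh:
        return fit_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# decoded-path exports
# ---------------------------------------------------------------------------

def write_paths_csv(paths, path) -> None:
    """Per-minute decoded states: columns subject_id, t, state."""
    frames = []
    for p in (paths.values() if isinstance(paths, dict) else paths):
        frames.append(pd.DataFrame({
            "subject_id": np.repeat(p.subject_id, p.T),
            "t": np.arange(1, p.T + 1),
            "state": p.states,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_segments_csv(paths, path) -> None:
    """Dwell segments with half-open [start, end) 1-based minute intervals."""
    frames = [p.segments_frame()
              for p in (paths.values() if isinstance(paths, dict) else paths)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
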