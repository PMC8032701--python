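"""Per-subject activity series and baseline-covariate containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig


@dataclass
class ActivitySeries:
    """One subject's per-minute activity counts with aligned covariates.

    Attributes
    ----------
    subject_id
        Opaque subject label.
    y
        Integer activity counts, shape ``(T,)``, all >= 0.  Minute index ``t``
        is implicit and 1-based: ``y[0]`` is minute 1.
    x
        Treatment covariates, shape ``(T, q)``.
    z
        Environmental covariates, shape ``(T, p)``.
    """

    subject_id: str
    y: np.ndarray
    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        T = self.y.shape[0]
        if T == 0:
            raise ValueError("series must contain at least one minute")
        if not np.issubdtype(self.y.dtype, np.integer):
            yf = np.asarray(self.y, dtype=float)
            yi = np.round(yf).astype(np.int64)
            if not np.allclose(yf, yi):
                raise ValueError("activity counts y must be integers")
            self.y = yi
        else:
            self.y = self.y.astype(np.int64)
        if np.any(self.y < 0):
            raise ValueError("activity counts y must be nonnegative")
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.x.shape[0] == 1 and T != 1:
            self.x = self.x.T
        if self.z.shape[0] == 1 and T != 1:
            self.z = self.z.T
        if self.x.shape[0] != T or self.z.shape[0] != T:
            raise ValueError(
                f"covariate rows ({self.x.shape[0]}, {self.z.shape[0]}) "
                f"must match T={T}"
            )

    @property
    def T(self) -> int:
        return self.y.shape[0]

    @property
    def q(self) -> int:
        return self.x.shape[1]

    @property
    def p(self) -> int:
        return self.z.shape[1]

    def check_config(self, config: ModelConfig) -> None:
        if self.q != config.q or self.p != config.p_dim:
            raise ValueError(
                f"covariate dimensions (q={self.q}, p={self.p}) do not match "
                f"config (q={config.q}, p_dim={config.p_dim})"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns subject_id, t, y, x_*, z_*."""
        data = {
            "subject_id": np.repeat(self.subject_id, self.T),
            "t": np.arange(1, self.T + 1),
            "y": self.y,
        }
        for j in range(self.q):
            data[f"x_{j}"] = self.x[:, j]
        for j in range(self.p):
            data[f"z_{j}"] = self.z[:, j]
        return pd.DataFrame(data)


def validate_baseline_table(table: pd.DataFrame, subject_ids=None) -> pd.DataFrame:
    """Validate a per-subject baseline covariate table ``W``.

    Expects a ``subject_id`` column (or index named subject_id) plus numeric
    covariate columns; no missing entries, unique subject ids, and — when
    ``subject_ids`` is given — exact agreement with the activity data's ids.
    Returns the table indexed by subject_id with covariates as float.
    """
    if "subject_id" in table.columns:
        table = table.set_index("subject_id")
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids in baseline table: {dupes}")
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"baseline table has missing entries in columns {bad}")
    table = table.astype(float)
    if subject_ids is not None:
        missing = set(map(str, subject_ids)) - set(map(str, table.index))
        if missing:
            raise ValueError(f"baseline table missing subjects: {sorted(missing)}")
    return table
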