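"""Survival dataset container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]


@dataclass
class SurvivalDataset:
    """Right-censored survival data.

    Attributes
    ----------
    time
        Observed times (event time or censoring time), strictly positive.
    event
        1 where the event was observed, 0 where the record is right-censored.
    covariate
        Optional binary covariate (0/1) per record, e.g. an age group.
    """

    time: np.ndarray
    event: np.ndarray
    covariate: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if self.time.size == 0:
            raise ValueError("dataset must contain at least one record")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = np.where(~(self.time > 0))[0]
            raise ValueError(f"times must be positive and finite (rows {bad.tolist()})")
        if not np.isin(self.event, (0, 1)).all():
            bad = np.where(~np.isin(self.event, (0, 1)))[0]
            raise ValueError(f"event flags must be 0 or 1 (rows {bad.tolist()})")
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=int)
            if self.covariate.shape != self.time.shape:
                raise ValueError("covariate must match the number of records")
            if not np.isin(self.covariate, (0, 1)).all():
                bad = np.where(~np.isin(self.covariate, (0, 1)))[0]
                raise ValueError(f"covariate must be binary 0/1 (rows {bad.tolist()})")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_censored(self) -> int:
        return len(self) - self.n_events

    @property
    def censored_mask(self) -> np.ndarray:
        return self.event == 0

    @property
    def has_covariate(self) -> bool:
        return self.covariate is not None

    def covariate_values(self) -> np.ndarray:
        """Covariate column, zeros when none was supplied."""
        if self.covariate is None:
            return np.zeros(len(self), dtype=int)
        return self.covariate

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time, "status": self.event}
        if self.covariate is not None:
            data["x"] = self.covariate
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        if "time" not in df.columns or "status" not in df.columns:
            raise ValueError("expected columns 'time' and 'status'")
        cov = df["x"].to_numpy() if "x" in df.columns else None
        return cls(df["time"].to_numpy(), df["status"].to_numpy(), cov)
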