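"""Target-illumination schedules.

A schedule is the ordered list of photo-excitation records (x, y, t) per
cell, exactly the bookkeeping format produced during targeted-illumination
experiments.  It drives both the simulator (where each record is a light
pulse) and the target-relative metrics (where consecutive records at the
same position form a segment of constant target position).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("x_px", "y_px", "t_s", "cell_id")


@dataclass(frozen=True)
class TargetSegment:
    """A stretch of pulses delivered at one fixed position."""

    x: float
    y: float
    t_start: float
    t_end: float
    n_pulses: int


class TargetSchedule:
    """Ordered (x, y, t, cell_id) photo-excitation records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``x_px, y_px, t_s, cell_id``.  Rows are sorted by
        (cell_id, t_s) on construction; per-cell times must be
        non-decreasing after sorting (always true) and are validated for
        finiteness.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"targets table is missing required column(s): {missing}")
        df = records.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("x_px", "y_px", "t_s"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if not np.isfinite(df[col]).all():
                raise ValueError(f"non-finite values in column {col!r}")
        df = df.sort_values(["cell_id", "t_s"], kind="stable").reset_index(drop=True)
        self.records = df

    # -- constructors -------------------------------------------------
    @classmethod
    def from_csv(cls, path: Union[str, Path, io.TextIOBase]) -> "TargetSchedule":
        return cls(pd.read_csv(path))

    @classmethod
    def from_pulses(
        cls, x: float, y: float, times: Iterable[float], cell_id: Union[int, str] = 0
    ) -> "TargetSchedule":
        times = list(times)
        return cls(
            pd.DataFrame(
                {
                    "x_px": [x] * len(times),
                    "y_px": [y] * len(times),
                    "t_s": times,
                    "cell_id": [cell_id] * len(times),
                }
            )
        )

    @classmethod
    def empty(cls) -> "TargetSchedule":
        return cls(pd.DataFrame({c: [] for c in REQUIRED_COLUMNS}))

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def cell_ids(self) -> list:
        return list(dict.fromkeys(self.records["cell_id"].tolist()))

    def for_cell(self, cell_id) -> pd.DataFrame:
        return self.records[self.records["cell_id"] == cell_id].reset_index(drop=True)

    def pulse_times(self, cell_id) -> np.ndarray:
        return self.for_cell(cell_id)["t_s"].to_numpy(dtype=float)

    def segments(self, cell_id, position_tol_px: float = 1.0) -> list[TargetSegment]:
        """Group consecutive pulses at (nearly) the same position.

        A move of more than ``position_tol_px`` starts a new segment; a
        segment's hold window runs from its first to its last pulse.
        """
        df = self.for_cell(cell_id)
        segments: list[TargetSegment] = []
        if df.empty:
            return segments
        xs, ys, ts = (df[c].to_numpy(dtype=float) for c in ("x_px", "y_px", "t_s"))
        start = 0
        for i in range(1, len(df) + 1):
            if i == len(df) or np.hypot(xs[i] - xs[start], ys[i] - ys[start]) > position_tol_px:
                segments.append(
                    TargetSegment(
                        x=float(np.mean(xs[start:i])),
                        y=float(np.mean(ys[start:i])),
                        t_start=float(ts[start]),
                        t_end=float(ts[i - 1]),
                        n_pulses=i - start,
                    )
                )
                start = i
        return segments

    def active_segment(self, cell_id, t: float) -> Union[TargetSegment, None]:
        """Most recent segment whose first pulse precedes time ``t``."""
        active = None
        for seg in self.segments(cell_id):
            if seg.t_start <= t:
                active = seg
        return active

    def to_csv(self, path: Union[str, Path]) -> None:
        self.records.to_csv(path, index=False)


def read_targets(path: Union[str, Path, io.TextIOBase]) -> TargetSchedule:
    """Read and validate a targets CSV (columns x_px, y_px, t_s, cell_id)."""
    return TargetSchedule.from_csv(path)
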