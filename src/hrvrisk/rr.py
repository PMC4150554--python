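"""RR-interval series: container, artifact filtering, and plain-text I/O.

An RR series is the sequence of inter-beat (R-peak to R-peak) intervals of a
short ECG recording, in seconds.  This module deliberately starts *after* beat
detection: waveform acquisition and QRS detection are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["RRSeries", "UnusableRecordingError", "filter_rr", "read_rr", "write_rr"]


class UnusableRecordingError(ValueError):
    """Raised when artifact filtering leaves too few beats to analyse."""


@dataclass(frozen=True)
class RRSeries:
    """An ordered sequence of inter-beat intervals for one recording.

    Parameters
    ----------
    intervals : array-like of float
        Inter-beat intervals in seconds, in temporal order.  All must be
        strictly positive and there must be at least two of them.
    """

    intervals: np.ndarray
    duration: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("an RR series needs at least two intervals")
        if not np.all(arr > 0):
            raise ValueError("all RR intervals must be strictly positive")
        object.__setattr__(self, "intervals", arr)
        object.__setattr__(self, "duration", float(arr.sum()))

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def times(self) -> np.ndarray:
        """Beat times (s): cumulative sum of the intervals."""
        return np.cumsum(self.intervals)


def filter_rr(
    series: RRSeries,
    min_s: float = 0.3,
    max_s: float = 2.0,
    max_rel_jump: float = 0.2,
) -> tuple[RRSeries, float]:
    """Remove physiologically implausible intervals and abrupt jumps.

    Stands in for the visual artifact exclusion a human scorer would apply:
    intervals outside ``[min_s, max_s]`` are dropped, as is any interval whose
    relative difference from the previously *retained* interval exceeds
    ``max_rel_jump``.  The first in-range interval anchors the jump rule.

    Returns
    -------
    (RRSeries, float)
        The cleaned series and the fraction of intervals removed.

    Raises
    ------
    UnusableRecordingError
        If fewer than two intervals survive.
    """
    if not (0 < min_s < max_s):
        raise ValueError("need 0 < min_s < max_s")
    kept: list[float] = []
    prev: float | None = None
    for x in series.intervals:
        if not (min_s <= x <= max_s):
            continue
        if prev is not None and abs(x - prev) / prev > max_rel_jump:
            continue
        kept.append(float(x))
        prev = float(x)
    removed = 1.0 - len(kept) / len(series)
    if len(kept) < 2:
        raise UnusableRecordingError(
            f"only {len(kept)} of {len(series)} intervals survived filtering"
        )
    return RRSeries(np.asarray(kept)), removed


def read_rr(path: Union[str, Path]) -> dict[str, RRSeries]:
    """Read RR series from plain text or CSV.

    Two layouts are accepted: one interval (seconds) per line, or long-format
    CSV with columns ``patient_id,interval_s``.  Returns a dict keyed by
    patient id (single-column files get the file stem as id).
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    if "patient_id" in first:
        df = pd.read_csv(path)
        return {
            str(pid): RRSeries(grp["interval_s"].to_numpy())
            for pid, grp in df.groupby("patient_id", sort=False)
        }
    vals = np.loadtxt(path, ndmin=1)
    return {path.stem: RRSeries(vals)}


def write_rr(series: RRSeries, path: Union[str, Path]) -> None:
    """Write a series as one interval per line (plain text)."""
    np.savetxt(path, series.intervals, fmt="%.6f")
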