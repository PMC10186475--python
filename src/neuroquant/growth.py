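"""Population-doubling statistics for serially passaged cultures.

Each passage seeds a counted number of cells and harvests the grown
culture; the per-passage doubling number is

    M = log2(n_grown / n_seeded)

Negative M is allowed (culture loss); a zero harvest is reported as a
-inf sentinel with a flag rather than an error, because real cultures
can crash.  The cumulative curve is the running sum of per-passage M —
the proliferative-rate curve of a long-term culture — reported raw, with
no smoothing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PassageRecord", "doublings", "cumulative_doublings", "read_growth_csv"]


@dataclass(frozen=True)
class PassageRecord:
    passage: int
    n_seeded: int
    n_grown: int
    days_in_passage: float | None = None

    def __post_init__(self):
        if self.n_seeded <= 0:
            raise ValueError("n_seeded must be > 0")
        if self.n_grown < 0:
            raise ValueError("n_grown must be >= 0")


def doublings(record: PassageRecord) -> float:
    """Per-passage population doublings M = log2(n_grown / n_seeded)."""
    if record.n_grown == 0:
        return -math.inf
    return math.log2(record.n_grown / record.n_seeded)


def cumulative_doublings(series: list[PassageRecord]) -> pd.DataFrame:
    """Per-passage and cumulative doubling curve for an ordered series.

    Returns one row per passage with M, cumulative M, and doublings per
    day where passage durations are given.  Gaps in passage numbering
    warn but do not invalidate the cumulative sum; a crashed passage
    (zero harvest, M = -inf) is flagged and propagates -inf downstream.
    """
    if not series:
        return pd.DataFrame(
            columns=["passage", "n_seeded", "n_grown", "m", "cumulative_m",
                     "doublings_per_day", "crashed"]
        )
    passages = [r.passage for r in series]
    if sorted(passages) != passages or len(set(passages)) != len(passages):
        raise ValueError("passage numbers must be strictly increasing")
    if any(b - a > 1 for a, b in zip(passages, passages[1:])):
        warnings.warn("gap in passage numbers; cumulative curve still defined",
                      stacklevel=2)

    m = np.array([doublings(r) for r in series])
    per_day = [
        (mi / r.days_in_passage) if (r.days_in_passage and math.isfinite(mi)) else np.nan
        for mi, r in zip(m, series)
    ]
    return pd.DataFrame(
        {
            "passage": passages,
            "n_seeded": [r.n_seeded for r in series],
            "n_grown": [r.n_grown for r in series],
            "m": m,
            "cumulative_m": np.cumsum(m),
            "doublings_per_day": per_day,
            "crashed": [r.n_grown == 0 for r in series],
        }
    )


def read_growth_csv(path) -> list[PassageRecord]:
    """Read passage counts from CSV columns (passage, n_seeded, n_grown[, days])."""
    df = pd.read_csv(path)
    missing = {"passage", "n_seeded", "n_grown"} - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    return [
        PassageRecord(
            passage=int(r.passage),
            n_seeded=int(r.n_seeded),
            n_grown=int(r.n_grown),
            days_in_passage=float(r.days) if "days" in df.columns and not pd.isna(r.days) else None,
        )
        for r in df.itertuples(index=False)
    ]
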