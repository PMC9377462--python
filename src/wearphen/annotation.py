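"""Activity-state annotation and standardized segment extraction.

Every jointly valid minute is assigned exactly one activity state with
precedence sleep > sedentary > active: minutes covered by the device sleep
log are *sleep*; remaining minutes with a zero step count are *sedentary*;
everything else is *active*.

High-resolution featurization operates on the longest uninterrupted run of
same-state minutes, truncated to a standard length per state: 20 minutes for
active, 60 for sedentary, 300 for sleep.  A state whose longest run falls
short of its standard length is not considered for that participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import ACTIVE, SEDENTARY, SLEEP, MinuteSeries

__all__ = [
    "Segment",
    "STANDARD_LENGTHS",
    "annotate_states",
    "longest_uninterrupted_run",
    "extract_standard_segment",
    "availability_profile",
]

#: standard segment lengths, minutes: first 20 min active, 1 h sedentary, 5 h sleep
STANDARD_LENGTHS = {ACTIVE: 20, SEDENTARY: 60, SLEEP: 300}


@dataclass(frozen=True)
class Segment:
    """A gap-free run of same-state minutes carrying the heart-rate values x_t."""

    participant_id: str
    state: str
    start: tuple[object, int]  # (day, minute-of-day)
    values: tuple[float, ...]
    nominal_length: int

    def __len__(self) -> int:
        return len(self.values)


def annotate_states(
    series: MinuteSeries, sleep_intervals: Optional[pd.DataFrame] = None
) -> MinuteSeries:
    """Assign sleep/sedentary/active to every jointly valid minute.

    A minute inside a sleep-log interval is sleep regardless of steps; a
    non-sleep minute with zero steps is sedentary; any other valid minute is
    active.  Minutes missing either stream keep a null state.
    """
    if sleep_intervals is None:
        sleep_intervals = series.sleep_intervals
    m = series.minutes.copy()
    if m.empty:
        return series.with_minutes(m)
    valid = m["hr"].notna() & m["steps"].notna()
    in_sleep = np.zeros(len(m), dtype=bool)
    times = m["time"]
    for row in sleep_intervals.itertuples(index=False):
        in_sleep |= ((times >= row.sleep_start) & (times < row.sleep_end)).to_numpy()
    state = np.full(len(m), None, dtype=object)
    state[valid & ~in_sleep] = ACTIVE
    state[(valid & ~in_sleep & (m["steps"] == 0)).to_numpy()] = SEDENTARY
    state[valid & in_sleep] = SLEEP
    m["state"] = state
    return series.with_minutes(m)


def _runs(series: MinuteSeries, state: str):
    """Yield (start_row, values) for maximal contiguous same-state runs.

    A run requires consecutive calendar minutes (no gaps in the record), the
    requested state throughout, and a valid heart-rate value at every minute.
    """
    m = series.minutes
    ok = (m["state"] == state) & m["hr"].notna()
    if not ok.any():
        return
    times = m["time"].to_numpy()
    idx = np.nonzero(ok.to_numpy())[0]
    # split where row indices jump or timestamps are not 1 minute apart
    breaks = np.nonzero(
        (np.diff(idx) != 1)
        | (np.diff(times[idx]) != np.timedelta64(1, "m"))
    )[0]
    for chunk in np.split(idx, breaks + 1):
        first = m.iloc[chunk[0]]
        yield (first["day"], int(first["minute"])), m["hr"].to_numpy()[chunk]


def longest_uninterrupted_run(series: MinuteSeries, state: str) -> Optional[Segment]:
    """The maximal run of consecutive valid minutes in ``state``.

    Ties are broken by earliest start.  Returns None when no minute of the
    state exists.
    """
    if state not in STANDARD_LENGTHS:
        raise ValueError(f"unknown activity state: {state!r}")
    best = None
    for start, values in _runs(series, state):
        if best is None or len(values) > len(best[1]):
            best = (start, values)
    if best is None:
        return None
    start, values = best
    return Segment(
        participant_id=series.participant_id,
        state=state,
        start=start,
        values=tuple(float(v) for v in values),
        nominal_length=len(values),
    )


def extract_standard_segment(series: MinuteSeries, state: str) -> Optional[Segment]:
    """First L minutes of the longest run; None when the run is shorter than L."""
    length = STANDARD_LENGTHS.get(state)
    if length is None:
        raise ValueError(f"unknown activity state: {state!r}")
    run = longest_uninterrupted_run(series, state)
    if run is None or len(run) < length:
        return None
    return Segment(
        participant_id=run.participant_id,
        state=state,
        start=run.start,
        values=run.values[:length],
        nominal_length=length,
    )


def availability_profile(cohort: Iterable[MinuteSeries]) -> pd.DataFrame:
    """Which feature categories are derivable for each participant.

    ``has_summary`` requires at least one valid day and at least one sleep-log
    interval starting on a valid day (the sleep-derived summary statistics are
    undefined otherwise).
    """
    rows = []
    for series in cohort:
        flags = {
            "participant_id": series.participant_id,
            "has_active": extract_standard_segment(series, ACTIVE) is not None,
            "has_sedentary": extract_standard_segment(series, SEDENTARY) is not None,
            "has_sleep": extract_standard_segment(series, SLEEP) is not None,
        }
        days = set(series.minutes["day"])
        logged = series.sleep_intervals
        has_log = len(logged) > 0 and any(
            s.date() in days for s in pd.to_datetime(logged["sleep_start"])
        )
        flags["has_summary"] = bool(days) and has_log
        rows.append(flags)
    return pd.DataFrame(
        rows,
        columns=["participant_id", "has_active", "has_sedentary", "has_sleep", "has_summary"],
    )
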