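"""Reading raw wearable streams and regularizing them to a 1-minute grid.

Consumer devices export heart rate either at regular 1-minute intervals or as
irregular bursts of 5/10/15-second samples, and step counts at 1-minute or
15-minute intervals.  Everything downstream works on a single regularized
representation: one record per calendar minute, with per-minute heart rate
(mean of in-minute samples), per-minute steps (coarse intervals allocated
uniformly), and an activity state filled in by :mod:`wearphen.annotation`.

Only days with at least 20 hours (1200 minutes) of jointly valid heart-rate
and step data are retained for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "MinuteSeries",
    "SLEEP",
    "SEDENTARY",
    "ACTIVE",
    "VALID_DAY_MINUTES",
    "read_recording",
    "resample_to_minutes",
    "filter_valid_days",
]

SLEEP = "SLEEP"
SEDENTARY = "SEDENTARY"
ACTIVE = "ACTIVE"

#: "at least 20 hours" of jointly valid heart-rate and step data per day
VALID_DAY_MINUTES = 1200


@dataclass(frozen=True)
class RawRecording:
    """One participant's streams before regularization.

    ``hr_samples`` has columns ``timestamp, bpm``; ``step_samples`` has
    ``interval_start, interval_seconds, steps``; ``sleep_intervals`` has
    ``sleep_start, sleep_end``.  Timestamps are timezone-naive local time.
    """

    participant_id: str
    hr_samples: pd.DataFrame
    step_samples: pd.DataFrame
    sleep_intervals: pd.DataFrame

    def __post_init__(self) -> None:
        for frame, col in ((self.hr_samples, "timestamp"), (self.step_samples, "interval_start")):
            ts = frame[col]
            if len(ts) > 1 and not ts.is_monotonic_increasing:
                raise ValueError(
                    f"participant {self.participant_id}: {col} not sorted ascending"
                )
        if (self.hr_samples["bpm"] <= 0).any():
            raise ValueError(f"participant {self.participant_id}: non-positive bpm")
        if (self.step_samples["steps"] < 0).any():
            raise ValueError(f"participant {self.participant_id}: negative step count")


@dataclass(frozen=True)
class MinuteSeries:
    """The 1-minute regularized, day-partitioned series.

    ``minutes`` carries one row per calendar minute of the covered span:
    ``time`` (minute start), ``day`` (date), ``minute`` (0..1439), ``hr``
    (bpm, NaN when missing), ``steps`` (NaN when missing) and ``state``
    (one of SLEEP/SEDENTARY/ACTIVE, or None while unannotated / for minutes
    where either stream is missing).
    """

    participant_id: str
    minutes: pd.DataFrame
    sleep_intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sleep_start", "sleep_end"])
    )

    @property
    def valid(self) -> pd.Series:
        """Minutes where both streams are present."""
        return self.minutes["hr"].notna() & self.minutes["steps"].notna()

    def with_minutes(self, minutes: pd.DataFrame) -> "MinuteSeries":
        return replace(self, minutes=minutes.reset_index(drop=True))


def _parse_times(frame: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    try:
        return pd.to_datetime(frame[col], format="ISO8601")
    except (ValueError, TypeError):
        # find the offending line for a useful message
        for i, raw in enumerate(frame[col]):
            try:
                pd.to_datetime(raw)
            except (ValueError, TypeError):
                raise ValueError(
                    f"{path}: malformed timestamp {raw!r} at data line {i + 1}"
                ) from None
        raise


def read_recording(
    hr_path: str | Path,
    steps_path: str | Path,
    sleep_path: str | Path | None = None,
) -> dict[str, RawRecording]:
    """Read the three CSV streams into one :class:`RawRecording` per participant.

    Participants absent from the sleep file get an empty sleep-interval table.
    Malformed timestamps and negative readings raise with the file named.
    """
    hr = pd.read_csv(hr_path)
    steps = pd.read_csv(steps_path)
    hr["timestamp"] = _parse_times(hr, "timestamp", hr_path)
    steps["interval_start"] = _parse_times(steps, "interval_start", steps_path)
    if sleep_path is not None:
        sleep = pd.read_csv(sleep_path)
        if len(sleep):
            sleep["sleep_start"] = _parse_times(sleep, "sleep_start", sleep_path)
            sleep["sleep_end"] = _parse_times(sleep, "sleep_end", sleep_path)
    else:
        sleep = pd.DataFrame(columns=["participant_id", "sleep_start", "sleep_end"])

    recordings = {}
    ids = sorted(set(hr["participant_id"]).union(steps["participant_id"]))
    for pid in ids:
        psleep = sleep[sleep["participant_id"] == pid] if len(sleep) else sleep
        recordings[str(pid)] = RawRecording(
            participant_id=str(pid),
            hr_samples=hr.loc[hr["participant_id"] == pid, ["timestamp", "bpm"]].reset_index(drop=True),
            step_samples=steps.loc[
                steps["participant_id"] == pid,
                ["interval_start", "interval_seconds", "steps"],
            ].reset_index(drop=True),
            sleep_intervals=psleep.reindex(columns=["sleep_start", "sleep_end"]).reset_index(drop=True),
        )
    return recordings


def _allocate_steps(count: int, n_minutes: int) -> np.ndarray:
    """Spread a coarse interval's steps uniformly; remainder to earliest minutes."""
    base, rem = divmod(int(count), n_minutes)
    out = np.full(n_minutes, base, dtype=float)
    out[:rem] += 1
    return out


def resample_to_minutes(rec: RawRecording) -> MinuteSeries:
    """Regularize both streams to the 1-minute grid.

    Per-minute heart rate is the arithmetic mean of all samples falling in
    [minute, minute+1); missing minutes stay NaN.  One-minute step records map
    directly; coarser intervals are allocated uniformly across their covered
    minutes with the remainder given to the earliest minutes, so totals are
    conserved.  The emitted span runs from the first to the last observation
    of either stream.
    """
    hr = rec.hr_samples
    steps = rec.step_samples
    if hr.empty and steps.empty:
        return MinuteSeries(rec.participant_id, _empty_minutes(), rec.sleep_intervals)

    bounds = []
    if not hr.empty:
        bounds.append((hr["timestamp"].iloc[0], hr["timestamp"].iloc[-1]))
    if not steps.empty:
        last_end = steps["interval_start"] + pd.to_timedelta(
            steps["interval_seconds"] - 1, unit="s"
        )
        bounds.append((steps["interval_start"].iloc[0], last_end.max()))
    start = min(b[0] for b in bounds).floor("min")
    end = max(b[1] for b in bounds).floor("min")
    index = pd.date_range(start, end, freq="min")

    frame = pd.DataFrame(
        {
            "time": index,
            "hr": np.nan,
            "steps": np.nan,
            "state": pd.Series([None] * len(index), dtype=object),
        }
    )
    frame["day"] = frame["time"].dt.date
    frame["minute"] = frame["time"].dt.hour * 60 + frame["time"].dt.minute
    frame = frame[["time", "day", "minute", "hr", "steps", "state"]]

    if not hr.empty:
        minute_of = hr["timestamp"].dt.floor("min")
        means = hr.groupby(minute_of)["bpm"].mean()
        pos = ((means.index - start) // pd.Timedelta(minutes=1)).astype(int)
        frame.loc[pos, "hr"] = means.to_numpy()

    if not steps.empty:
        ends = steps["interval_start"] + pd.to_timedelta(steps["interval_seconds"], unit="s")
        if (steps["interval_start"].iloc[1:].reset_index(drop=True) < ends.iloc[:-1].reset_index(drop=True)).any():
            raise ValueError(
                f"participant {rec.participant_id}: overlapping step intervals"
            )
        step_col = frame["steps"].to_numpy()
        firsts = (
            (steps["interval_start"].dt.floor("min") - start) // pd.Timedelta(minutes=1)
        ).to_numpy(dtype=int)
        secs_arr = steps["interval_seconds"].to_numpy()
        counts_arr = steps["steps"].to_numpy(dtype=float)
        regular = secs_arr == 60
        if regular.any():
            pos = firsts[regular]
            cur = step_col[pos]
            cur[np.isnan(cur)] = 0
            step_col[pos] = cur + counts_arr[regular]
        for first, secs, count in zip(
            firsts[~regular], secs_arr[~regular], counts_arr[~regular]
        ):
            if secs < 60:
                # sub-minute record: accumulate into its containing minute
                step_col[first] = (0 if np.isnan(step_col[first]) else step_col[first]) + count
            else:
                n_min = max(1, int(round(secs / 60.0)))
                alloc = _allocate_steps(count, n_min)
                sl = slice(first, first + n_min)
                old = step_col[sl]
                old[np.isnan(old)] = 0
                step_col[sl] = old + alloc
        frame["steps"] = step_col

    return MinuteSeries(rec.participant_id, frame, rec.sleep_intervals)


def _empty_minutes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": pd.Series(dtype="datetime64[ns]"),
            "day": pd.Series(dtype=object),
            "minute": pd.Series(dtype=int),
            "hr": pd.Series(dtype=float),
            "steps": pd.Series(dtype=float),
            "state": pd.Series(dtype=object),
        }
    )


def filter_valid_days(series: MinuteSeries, min_minutes: int = VALID_DAY_MINUTES) -> MinuteSeries:
    """Retain only calendar days with >= ``min_minutes`` jointly valid minutes."""
    m = series.minutes
    if m.empty:
        return series
    ok = m["hr"].notna() & m["steps"].notna()
    per_day = ok.groupby(m["day"]).sum()
    keep = set(per_day.index[per_day >= min_minutes])
    return series.with_minutes(m[m["day"].isin(keep)])
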