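"""Wearable summary statistics: resting heart rate and 10 activity/sleep features.

The summary block complements the high-resolution segment features with the
kind of statistics commonly reported for consumer wearables: mean daily
durations per activity state, mean daily step count, circadian sleep/wake
timing (encoded on the unit circle to respect the 24-hour wrap-around), and
sleep-episode statistics.  Resting heart rate is the mean heart rate over all
valid minutes with a step count of at most 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import ACTIVE, SEDENTARY, SLEEP, MinuteSeries

__all__ = [
    "SummaryFeatures",
    "SUMMARY_FEATURE_NAMES",
    "RESTING_HR_STEP_THRESHOLD",
    "resting_heart_rate",
    "mean_daily_state_durations",
    "sleep_wake_statistics",
    "encode_time_sinusoidal",
    "summarize",
]

#: minutes with steps <= this threshold contribute to resting heart rate
RESTING_HR_STEP_THRESHOLD = 100

#: the 10 summary features (resting heart rate is carried separately)
SUMMARY_FEATURE_NAMES = (
    "mean_daily_active_min",
    "mean_daily_sedentary_min",
    "mean_daily_sleep_min",
    "mean_daily_steps",
    "sin_wake",
    "cos_wake",
    "sin_sleep_onset",
    "cos_sleep_onset",
    "mean_sleep_episode_min",
    "n_sleep_episodes_per_day",
)


@dataclass(frozen=True)
class SummaryFeatures:
    resting_hr: float
    mean_daily_active_min: float
    mean_daily_sedentary_min: float
    mean_daily_sleep_min: float
    mean_daily_steps: float
    sin_wake: float
    cos_wake: float
    sin_sleep_onset: float
    cos_sleep_onset: float
    mean_sleep_episode_min: float
    n_sleep_episodes_per_day: float

    def to_row(self) -> dict[str, float]:
        return {"resting_hr": self.resting_hr} | {
            k: getattr(self, k) for k in SUMMARY_FEATURE_NAMES
        }


def resting_heart_rate(series: MinuteSeries) -> float:
    """Mean bpm over valid minutes with steps <= 100 (boundary inclusive).

    Returns NaN with a warning when no minute qualifies.
    """
    m = series.minutes
    ok = m["hr"].notna() & m["steps"].notna() & (m["steps"] <= RESTING_HR_STEP_THRESHOLD)
    if not ok.any():
        warnings.warn(
            f"participant {series.participant_id}: no qualifying minutes for "
            "resting heart rate",
            stacklevel=2,
        )
        return math.nan
    return float(m.loc[ok, "hr"].mean())


def mean_daily_state_durations(series: MinuteSeries) -> tuple[float, float, float]:
    """(active, sedentary, sleep) minutes per day, averaged over days."""
    m = series.minutes
    days = m["day"].unique()
    if len(days) == 0:
        return (0.0, 0.0, 0.0)
    out = []
    for state in (ACTIVE, SEDENTARY, SLEEP):
        per_day = (m["state"] == state).groupby(m["day"]).sum()
        out.append(float(per_day.reindex(days, fill_value=0).mean()))
    return tuple(out)  # type: ignore[return-value]


def _circular_mean_hours(hours: np.ndarray) -> float:
    """Mean clock time (in hours, [0, 24)) by vector averaging on the circle."""
    ang = hours / 24 * 2 * math.pi
    mean_ang = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return (mean_ang / (2 * math.pi) * 24) % 24


def sleep_wake_statistics(
    sleep_intervals: pd.DataFrame, valid_days: set
) -> tuple[float, float, float, float]:
    """(mean wake time h, mean onset time h, mean episode min, episodes/day).

    The day's main sleep episode is its longest logged interval; its start is
    the sleep onset and its end the wake time, averaged circularly over days.
    Episode statistics cover all intervals starting on valid days; episodes
    per day averages over the days that have at least one episode.
    """
    if len(sleep_intervals) == 0:
        return (math.nan, math.nan, math.nan, math.nan)
    iv = sleep_intervals.copy()
    iv["sleep_start"] = pd.to_datetime(iv["sleep_start"])
    iv["sleep_end"] = pd.to_datetime(iv["sleep_end"])
    iv = iv[iv["sleep_start"].dt.date.isin(valid_days)]
    if len(iv) == 0:
        return (math.nan, math.nan, math.nan, math.nan)
    iv["day"] = iv["sleep_start"].dt.date
    iv["duration_min"] = (iv["sleep_end"] - iv["sleep_start"]).dt.total_seconds() / 60

    main = iv.loc[iv.groupby("day")["duration_min"].idxmax()]
    onset_h = (
        main["sleep_start"].dt.hour + main["sleep_start"].dt.minute / 60
    ).to_numpy(dtype=float)
    wake_h = (
        main["sleep_end"].dt.hour + main["sleep_end"].dt.minute / 60
    ).to_numpy(dtype=float)
    mean_wake = _circular_mean_hours(wake_h)
    mean_onset = _circular_mean_hours(onset_h)
    mean_episode = float(iv["duration_min"].mean())
    episodes_per_day = float(iv.groupby("day").size().mean())
    return (mean_wake, mean_onset, mean_episode, episodes_per_day)


def encode_time_sinusoidal(t: float) -> tuple[float, float]:
    """Clock time in hours -> (sin, cos) point on the 24-hour circle."""
    if not 0 <= t < 24:
        raise ValueError(f"time of day must lie in [0, 24): got {t}")
    ang = 2 * math.pi * t / 24
    return (math.sin(ang), math.cos(ang))


def summarize(
    series: MinuteSeries, sleep_intervals: Optional[pd.DataFrame] = None
) -> SummaryFeatures:
    """Assemble resting heart rate plus the 10 summary features.

    Sleep-derived fields are NaN when no usable sleep log exists; duration and
    step statistics are still computed.
    """
    if sleep_intervals is None:
        sleep_intervals = series.sleep_intervals
    m = series.minutes
    active, sedentary, sleep = mean_daily_state_durations(series)
    days = set(m["day"].unique())
    if days:
        daily_steps = m.groupby("day")["steps"].sum(min_count=1)
        mean_steps = float(daily_steps.mean())
    else:
        mean_steps = math.nan
    wake, onset, episode_min, episodes = sleep_wake_statistics(sleep_intervals, days)
    if math.isnan(wake):
        sin_w = cos_w = sin_o = cos_o = math.nan
    else:
        sin_w, cos_w = encode_time_sinusoidal(wake)
        sin_o, cos_o = encode_time_sinusoidal(onset)
    return SummaryFeatures(
        resting_hr=resting_heart_rate(series),
        mean_daily_active_min=active,
        mean_daily_sedentary_min=sedentary,
        mean_daily_sleep_min=sleep,
        mean_daily_steps=mean_steps,
        sin_wake=sin_w,
        cos_wake=cos_w,
        sin_sleep_onset=sin_o,
        cos_sleep_onset=cos_o,
        mean_sleep_episode_min=episode_min,
        n_sleep_episodes_per_day=episodes,
    )
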