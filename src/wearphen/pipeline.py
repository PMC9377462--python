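"""End-to-end assembly: raw recordings -> participant feature table.

One row per participant: age, gender, wearable-derived resting heart rate,
the 10 summary statistics, and up to 66 high-resolution features named
``<feature>.<state>``.  Participants lacking a standardized segment for some
state carry NaN in that state's block; modeling rows are restricted to
participants with complete feature sets, mirroring the training-set
construction of the cohort analysis.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .annotation import annotate_states
from .catch22 import FEATURE_NAMES, high_res_features
from .io import MinuteSeries, RawRecording, filter_valid_days, resample_to_minutes
from .summary import SUMMARY_FEATURE_NAMES, summarize

__all__ = [
    "process_recording",
    "build_feature_table",
    "complete_cases",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    ["age", "gender", "resting_hr"]
    + list(SUMMARY_FEATURE_NAMES)
    + [f"{name}.{state}" for state in ("active", "sedentary", "sleep") for name in FEATURE_NAMES]
)


def process_recording(rec: RawRecording) -> MinuteSeries:
    """Regularize, filter to valid days, and annotate one recording."""
    series = resample_to_minutes(rec)
    series = filter_valid_days(series)
    return annotate_states(series)


def build_feature_table(
    recordings: Mapping[str, RawRecording] | Iterable[RawRecording],
    demographics: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Participant feature rows from raw recordings.

    ``demographics`` (columns ``participant_id, age, sex``) supplies the
    baseline features; gender is encoded 0 = female, 1 = male.
    """
    if isinstance(recordings, Mapping):
        recs = list(recordings.values())
    else:
        recs = list(recordings)
    demo = None
    if demographics is not None:
        demo = demographics.set_index("participant_id")
    rows = []
    for rec in recs:
        series = process_recording(rec)
        row: dict[str, float] = {"participant_id": rec.participant_id}
        if demo is not None and rec.participant_id in demo.index:
            row["age"] = float(demo.loc[rec.participant_id, "age"])
            row["gender"] = 1.0 if demo.loc[rec.participant_id, "sex"] == "male" else 0.0
        summary = summarize(series)
        row.update(summary.to_row())
        row.update(high_res_features(series).to_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    # make every expected column present even if no participant reached it
    for col in FEATURE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table


def complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with every feature present (the modeling training set)."""
    return table.dropna(subset=[c for c in FEATURE_COLUMNS if c in table.columns])
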