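import numpy as np
import pandas as pd
import pytest

from wearphen import (
    SimConfig,
    build_feature_table,
    clinical_labels_frame,
    complete_cases,
    simulate_cohort,
)
from wearphen.io import MinuteSeries


def make_minute_series(
    hr,
    steps,
    participant_id="T0",
    start="2019-03-04 00:00:00",
    sleep_intervals=None,
) -> MinuteSeries:
    """Hand-rolled minute series for unit tests (NaN = missing)."""
    hr = np.asarray(hr, dtype=float)
    steps = np.asarray(steps, dtype=float)
    times = pd.date_range(start, periods=hr.size, freq="min")
    frame = pd.DataFrame(
        {
            "time": times,
            "day": times.date,
            "minute": times.hour * 60 + times.minute,
            "hr": hr,
            "steps": steps,
            "state": pd.Series([None] * hr.size, dtype=object),
        }
    )
    if sleep_intervals is None:
        sleep = pd.DataFrame(columns=["sleep_start", "sleep_end"])
    else:
        sleep = pd.DataFrame(
            [
                {"sleep_start": pd.Timestamp(a), "sleep_end": pd.Timestamp(b)}
                for a, b in sleep_intervals
            ]
        )
    return MinuteSeries(participant_id=participant_id, minutes=frame, sleep_intervals=sleep)


def _cohort_table(config: SimConfig) -> pd.DataFrame:
    cohort = simulate_cohort(config)
    table = complete_cases(
        build_feature_table(cohort.recordings, cohort.labs[["participant_id", "age", "sex"]])
    )
    labels = clinical_labels_frame(cohort.labs)
    return table.merge(labels, on="participant_id")


@pytest.fixture(scope="session")
def effect_cohort():
    """400 participants with a planted sedentary-amplitude risk effect."""
    return _cohort_table(
        SimConfig(
            n_participants=400,
            seed=11,
            effect_plan={("SEDENTARY", "amplitude"): 1.0},
        )
    )


@pytest.fixture(scope="session")
def null_cohort():
    """300 participants, balanced labels, no planted effect."""
    return _cohort_table(SimConfig(n_participants=300, seed=21))


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-participant cohort for pipeline-level checks."""
    return simulate_cohort(
        SimConfig(n_participants=10, seed=5, effect_plan={("SEDENTARY", "amplitude"): 1.0})
    )
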