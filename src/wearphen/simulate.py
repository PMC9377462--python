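"""Device-realistic synthetic wearable cohorts with plantable risk effects.

The generator emulates the recording irregularities of consumer wrist
devices observed in free-living cohorts: heart rate arriving either at
regular 1-minute intervals or as irregular 5/10/15-second bursts, steps at
1-minute or 15-minute intervals, contiguous missing heart-rate stretches
averaging 94.9 (SD 85.8) minutes per day, one main nocturnal sleep episode
per night with occasional naps, and 3-5 recorded days per participant.

Heart rate follows a discrete-time mean-reverting (AR(1)) process with
state-specific level and noise (sleep < sedentary < active).  An *effect
plan* maps (activity state, dynamic property) pairs to effect sizes: at-risk
participants receive amplified oscillations ("amplitude") or heavy spikes
("spikiness") in the given state, planting a detectable association between
within-state heart-rate dynamics and the risk label.  Laboratory values are
drawn so the clinical threshold predicates reproduce the intended labels,
and polygenic scores are standard normal with optional risk-tail shifts.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ACTIVE, SEDENTARY, SLEEP, RawRecording

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "write_cohort"]

# the polygenic scores used for the three genomic targets
PGS_LIPIDS = (
    "PGS000060", "PGS000061", "PGS000062", "PGS000063", "PGS000065",
    "PGS000115", "PGS000192", "PGS000309", "PGS000310", "PGS000311",
    "PGS000340", "PGS000677", "PGS000688", "PGS000699",
)
PGS_BP = ("PGS000301", "PGS000302")
PGS_OBESITY = ("PGS000298",)

_STATE_MEANS = {SLEEP: 55.0, SEDENTARY: 68.0, ACTIVE: 95.0}
_STATE_NOISE = {SLEEP: 1.2, SEDENTARY: 2.2, ACTIVE: 4.5}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``effect_plan`` maps ``(state, property)`` to an effect size, with
    property one of ``amplitude`` (bpm of added within-state oscillation for
    at-risk participants) or ``spikiness`` (bpm scale of sporadic spikes).
    ``missing_minutes_mean``/``sd`` parametrize the truncated-normal daily
    total of missing heart-rate minutes, placed as contiguous stretches.
    """

    n_participants: int = 100
    days_min: int = 3
    days_max: int = 5
    burst_dialect_fraction: float = 0.5  # participants with 5/10/15-s hr bursts
    coarse_step_fraction: float = 0.3  # participants with 15-min step records
    missing_minutes_mean: float = 94.9
    missing_minutes_sd: float = 85.8
    missing_minutes_cap: float = 200.0  # keeps every generated day valid
    risk_prevalence: float = 0.5
    effect_plan: Mapping[tuple[str, str], float] = field(default_factory=dict)
    nap_probability: float = 0.15
    pgs_tail_shift: float = 0.0  # added to at-risk participants' first lipid score
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.risk_prevalence <= 1:
            raise ValueError("risk_prevalence must be a probability")
        for (state, prop), size in self.effect_plan.items():
            if state not in (SLEEP, SEDENTARY, ACTIVE):
                raise ValueError(f"effect plan references unknown state {state!r}")
            if prop not in ("amplitude", "spikiness"):
                raise ValueError(f"unknown dynamic property {prop!r}")
            if size < 0:
                raise ValueError("effect sizes must be non-negative")


@dataclass
class SimulatedCohort:
    recordings: dict[str, RawRecording]
    labs: pd.DataFrame
    pgs: pd.DataFrame
    pgs_map: pd.DataFrame
    true_labels: pd.DataFrame
    config: SimConfig


def _day_schedule(rng: np.random.Generator, nap: bool) -> tuple[np.ndarray, np.ndarray]:
    """States and steps for one calendar day (1440 minutes).

    Guarantees one active bout of >= 25 min, one sedentary stretch of >= 75
    min aligned to the 15-minute grid, and >= 380 sleep minutes from
    midnight, so every standardized segment is derivable.
    """
    state = np.full(1440, SEDENTARY, dtype=object)
    steps = np.zeros(1440)

    wake = int(rng.integers(385, 415))  # ~06:25-06:55
    onset = int(rng.integers(1385, 1415))  # ~23:05-23:35
    state[:wake] = SLEEP
    state[onset:] = SLEEP

    def light_block(a: int, b: int) -> None:
        state[a:b] = ACTIVE
        steps[a:b] = rng.poisson(18, b - a) + 1

    # morning routine, guaranteed active bout, guaranteed sedentary stretch
    light_block(wake, wake + int(rng.integers(20, 35)))
    bout_start = int(rng.integers(460, 490))
    bout_len = int(rng.integers(25, 41))
    state[bout_start : bout_start + bout_len] = ACTIVE
    steps[bout_start : bout_start + bout_len] = rng.poisson(95, bout_len) + 5

    sed_start = 540  # 09:00, aligned to the 15-min step grid
    sed_len = int(rng.choice([75, 90, 105]))
    state[sed_start : sed_start + sed_len] = SEDENTARY
    steps[sed_start : sed_start + sed_len] = 0

    # afternoon/evening: alternating light-activity and sedentary blocks
    t = sed_start + sed_len
    while t < onset:
        length = int(rng.integers(10, 31))
        end = min(t + length, onset)
        if rng.random() < 0.5:
            light_block(t, end)
        t = end

    if nap:
        nap_start = int(rng.integers(840, 900))
        nap_len = int(rng.integers(30, 60))
        state[nap_start : nap_start + nap_len] = SLEEP
        steps[nap_start : nap_start + nap_len] = 0
    return state, steps


def _hr_process(
    rng: np.random.Generator,
    states: np.ndarray,
    at_risk: bool,
    effect_plan: Mapping[tuple[str, str], float],
) -> np.ndarray:
    """Mean-reverting heart rate with optional risk-modulated dynamics."""
    from scipy.signal import lfilter

    n = states.size
    phi = 0.85
    level = np.empty(n)
    sigma = np.empty(n)
    for state in (SLEEP, SEDENTARY, ACTIVE):
        sel = states == state
        level[sel] = _STATE_MEANS[state]
        sigma[sel] = _STATE_NOISE[state]
    eps = rng.normal(0, 1, n) * sigma
    x = lfilter([1.0], [1.0, -phi], eps)
    hr = level + x
    if at_risk and effect_plan:
        t = np.arange(n)
        for state in (SLEEP, SEDENTARY, ACTIVE):
            sel = states == state
            amp = effect_plan.get((state, "amplitude"), 0.0)
            if amp > 0:
                # half-wave-rectified oscillation: recurrent upward surges,
                # skewing the within-state distribution away from its mean
                wave = np.sin(2 * math.pi * t[sel] / 18.0)
                hr[sel] += 8.0 * amp * np.maximum(wave, 0.0)
            spike = effect_plan.get((state, "spikiness"), 0.0)
            if spike > 0:
                hit = sel & (rng.random(n) < 0.06)
                hr[hit] += rng.exponential(12.0 * spike, int(hit.sum()))
    return np.clip(hr, 35, 210)


def _missing_mask(
    rng: np.random.Generator, config: SimConfig, n_days: int
) -> np.ndarray:
    """Contiguous missing stretches in the 11:00-23:00 zone of each day."""
    mask = np.zeros(n_days * 1440, dtype=bool)
    for d in range(n_days):
        total = rng.normal(config.missing_minutes_mean, config.missing_minutes_sd)
        total = int(np.clip(total, 0, config.missing_minutes_cap))
        n_stretch = int(rng.integers(1, 4))
        parts = np.sort(rng.choice(np.arange(1, total), size=n_stretch - 1, replace=False)) if total > n_stretch > 1 else []
        lengths = np.diff(np.concatenate([[0], parts, [total]])).astype(int) if total else []
        zone_start, zone_end = 660, 1380
        cursor = zone_start + int(rng.integers(0, 60))
        for length in lengths:
            if length <= 0:
                continue
            start = min(cursor, zone_end - length)
            mask[d * 1440 + start : d * 1440 + start + int(length)] = True
            gap = int(rng.integers(15, 90))
            cursor = start + int(length) + gap
    return mask


def _draw_labs(rng: np.random.Generator, at_risk: bool, sex: str) -> dict[str, float]:
    """Laboratory values consistent with the intended omnibus risk label."""
    labs = {
        "sbp": float(rng.normal(120, 9)),
        "dbp": float(rng.normal(75, 6)),
        "triglycerides": float(rng.normal(1.2, 0.35)),
        "total_cholesterol": float(rng.normal(5.1, 0.55)),
        "hdl": float(rng.normal(1.5, 0.2)),
        "ldl": float(rng.normal(3.1, 0.45)),
        "glucose": float(rng.normal(5.2, 0.35)),
        "waist": float(rng.normal(80 if sex == "female" else 88, 5)),
        "bmi": float(rng.normal(23.5, 1.6)),
    }
    # keep the intended negatives clear of every threshold
    caps = {
        "sbp": 139.0, "dbp": 89.5, "triglycerides": 2.25, "total_cholesterol": 6.1,
        "ldl": 4.0, "glucose": 5.95, "waist": 99.0 if sex == "male" else 89.0,
        "bmi": 27.3,
    }
    for k, cap in caps.items():
        labs[k] = min(labs[k], cap)
    labs["hdl"] = max(labs["hdl"], 1.05)
    if at_risk:
        groups = ["bp", "lipids", "obesity", "glucose"]
        k = 1 + rng.binomial(2, 0.2)
        for group in rng.choice(groups, size=k, replace=False):
            if group == "bp":
                labs["sbp"] = float(141 + rng.exponential(12))
            elif group == "lipids":
                which = rng.choice(["triglycerides", "total_cholesterol", "hdl", "ldl"])
                if which == "hdl":
                    labs["hdl"] = float(max(0.5, 0.99 - rng.exponential(0.1)))
                elif which == "triglycerides":
                    labs["triglycerides"] = float(2.31 + rng.exponential(0.5))
                elif which == "total_cholesterol":
                    labs["total_cholesterol"] = float(6.21 + rng.exponential(0.5))
                else:
                    labs["ldl"] = float(4.11 + rng.exponential(0.5))
            elif group == "obesity":
                labs["bmi"] = float(27.51 + rng.exponential(1.5))
            else:
                labs["glucose"] = float(6.01 + rng.exponential(0.6))
    return labs


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate raw recordings, labs, polygenic scores and true labels."""
    rng = np.random.default_rng(config.seed)
    recordings: dict[str, RawRecording] = {}
    lab_rows = []
    label_rows = []
    pgs_rows = []
    origin = pd.Timestamp("2019-03-04 00:00:00")

    all_pgs = (
        [(p, "lipids") for p in PGS_LIPIDS]
        + [(p, "bp") for p in PGS_BP]
        + [(p, "obesity") for p in PGS_OBESITY]
    )
    # one lipid score runs protective-direction to exercise both tail rules
    pgs_map = pd.DataFrame(
        {
            "pgs_id": [p for p, _ in all_pgs],
            "target": [t for _, t in all_pgs],
            "risk_direction": [
                "low_score_risky" if p == "PGS000065" else "high_score_risky"
                for p, _ in all_pgs
            ],
        }
    )

    for i in range(config.n_participants):
        pid = f"P{i:04d}"
        n_days = int(rng.integers(config.days_min, config.days_max + 1))
        at_risk = bool(rng.random() < config.risk_prevalence)
        sex = "female" if rng.random() < 0.5 else "male"
        age = float(rng.integers(21, 70))

        states = []
        steps = []
        sleep_rows = []
        for d in range(n_days):
            st, sp = _day_schedule(rng, nap=rng.random() < config.nap_probability)
            states.append(st)
            steps.append(sp)
        states = np.concatenate(states)
        steps_per_min = np.concatenate(steps)
        # nightly sleep-log intervals matching the schedule's sleep minutes
        sleep_idx = np.nonzero(states == SLEEP)[0]
        splits = np.nonzero(np.diff(sleep_idx) != 1)[0]
        for chunk in np.split(sleep_idx, splits + 1):
            sleep_rows.append(
                {
                    "participant_id": pid,
                    "sleep_start": origin + pd.Timedelta(minutes=int(chunk[0])),
                    "sleep_end": origin + pd.Timedelta(minutes=int(chunk[-1]) + 1),
                }
            )

        hr = _hr_process(rng, states, at_risk, config.effect_plan)
        missing = _missing_mask(rng, config, n_days)

        # emit heart-rate samples in the participant's dialect
        use_burst = rng.random() < config.burst_dialect_fraction
        present = np.nonzero(~missing)[0]
        if use_burst:
            intervals = rng.choice([5, 10, 15], size=present.size)
            sec_parts = []
            val_parts = []
            for iv in (5, 10, 15):
                sel = present[intervals == iv]
                if sel.size == 0:
                    continue
                offs = np.arange(0, 60, iv)
                secs = (sel[:, None] * 60 + offs[None, :]).ravel()
                vals = (
                    hr[sel][:, None] + rng.normal(0, 0.8, (sel.size, offs.size))
                ).ravel()
                sec_parts.append(secs)
                val_parts.append(vals)
            secs = np.concatenate(sec_parts)
            order = np.argsort(secs, kind="stable")
            hr_frame = pd.DataFrame(
                {
                    "timestamp": origin + pd.to_timedelta(secs[order], unit="s"),
                    "bpm": np.round(np.concatenate(val_parts)[order], 1),
                }
            )
        else:
            hr_frame = pd.DataFrame(
                {
                    "timestamp": origin + pd.to_timedelta(present, unit="m"),
                    "bpm": np.round(hr[present], 1),
                }
            )

        # step records in the participant's dialect
        coarse = rng.random() < config.coarse_step_fraction
        if coarse:
            n_blocks = states.size // 15
            totals = steps_per_min[: n_blocks * 15].reshape(n_blocks, 15).sum(axis=1)
            step_frame = pd.DataFrame(
                {
                    "interval_start": origin
                    + pd.to_timedelta(np.arange(n_blocks) * 15, unit="m"),
                    "interval_seconds": 900,
                    "steps": totals.astype(int),
                }
            )
        else:
            step_frame = pd.DataFrame(
                {
                    "interval_start": origin
                    + pd.to_timedelta(np.arange(states.size), unit="m"),
                    "interval_seconds": 60,
                    "steps": steps_per_min.astype(int),
                }
            )

        recordings[pid] = RawRecording(
            participant_id=pid,
            hr_samples=hr_frame,
            step_samples=step_frame,
            sleep_intervals=pd.DataFrame(
                sleep_rows, columns=["participant_id", "sleep_start", "sleep_end"]
            )[["sleep_start", "sleep_end"]],
        )

        labs = _draw_labs(rng, at_risk, sex)
        lab_rows.append({"participant_id": pid, "age": age, "sex": sex} | labs)
        label_rows.append({"participant_id": pid, "at_risk": at_risk})

        scores = rng.normal(0, 1, len(all_pgs))
        if at_risk and config.pgs_tail_shift:
            scores[0] += config.pgs_tail_shift
        for (pgs_id, _), s in zip(all_pgs, scores):
            pgs_rows.append(
                {"participant_id": pid, "pgs_id": pgs_id, "score": float(s)}
            )

    return SimulatedCohort(
        recordings=recordings,
        labs=pd.DataFrame(lab_rows),
        pgs=pd.DataFrame(pgs_rows),
        pgs_map=pgs_map,
        true_labels=pd.DataFrame(label_rows),
        config=config,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the CSV schemas the ingestion stage consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hr_parts = []
    step_parts = []
    sleep_parts = []
    for pid, rec in cohort.recordings.items():
        hr = rec.hr_samples.copy()
        hr.insert(0, "participant_id", pid)
        hr_parts.append(hr)
        st = rec.step_samples.copy()
        st.insert(0, "participant_id", pid)
        step_parts.append(st)
        sl = rec.sleep_intervals.copy()
        if len(sl):
            sl.insert(0, "participant_id", pid)
            sleep_parts.append(sl)
    paths = {
        "hr": out / "heart_rate.csv",
        "steps": out / "steps.csv",
        "sleep": out / "sleep_log.csv",
        "labs": out / "labs.csv",
        "pgs": out / "pgs.csv",
        "pgs_map": out / "pgs_map.csv",
        "true_labels": out / "true_labels.csv",
    }
    pd.concat(hr_parts).to_csv(paths["hr"], index=False)
    pd.concat(step_parts).to_csv(paths["steps"], index=False)
    sleep = (
        pd.concat(sleep_parts)
        if sleep_parts
        else pd.DataFrame(columns=["participant_id", "sleep_start", "sleep_end"])
    )
    sleep.to_csv(paths["sleep"], index=False)
    cohort.labs.to_csv(paths["labs"], index=False)
    cohort.pgs.to_csv(paths["pgs"], index=False)
    cohort.pgs_map.to_csv(paths["pgs_map"], index=False)
    cohort.true_labels.to_csv(paths["true_labels"], index=False)
    return paths
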