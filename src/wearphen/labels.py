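"""Clinical and genomic binary risk targets.

Clinical targets derive from nine laboratory measurements compared against
fixed thresholds (all strict inequalities): systolic blood pressure >140 mm Hg,
diastolic >90 mm Hg, triglycerides >2.3 mmol/L, total cholesterol >6.2 mmol/L,
HDL <1 mmol/L, LDL >4.1 mmol/L, fasting glucose >6 mmol/L, waist circumference
>100 cm (male) / >90 cm (female), BMI >27.5 kg/m^2.  Four targets are formed:
``bp_abnormal`` (I-II), ``lipids_abnormal`` (III-VI), ``obesity`` (VIII-IX)
and the omnibus ``anyRISKoutof9`` (any of I-IX).

Genomic targets flag membership in the risk tail of any relevant polygenic
score (PGS): 14 scores map to lipid abnormalities, 2 to blood pressure, 1 to
obesity.  A participant is at high genomic risk for a target when any of its
scores falls in the top decile (for scores where high values are risky) or
bottom decile (otherwise); 85/15 and 80/20 cut-offs are supported for
sensitivity analyses.  Genomic risk is independent of age, so models of these
targets must never receive age as a feature; the flag is carried with the
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "LabPanel",
    "RiskLabels",
    "CLINICAL_TARGETS",
    "GENOMIC_TARGETS",
    "clinical_labels",
    "clinical_labels_frame",
    "genomic_labels",
]

CLINICAL_TARGETS = ("bp_abnormal", "lipids_abnormal", "obesity", "anyRISKoutof9")
GENOMIC_TARGETS = ("genomic_lipids", "genomic_bp", "genomic_obesity")

_REQUIRED = (
    "sbp",
    "dbp",
    "triglycerides",
    "total_cholesterol",
    "hdl",
    "ldl",
    "glucose",
    "waist",
    "bmi",
    "sex",
)


@dataclass(frozen=True)
class LabPanel:
    """One participant's laboratory screening measurements."""

    sbp: float
    dbp: float
    triglycerides: float
    total_cholesterol: float
    hdl: float
    ldl: float
    glucose: float
    waist: float
    bmi: float
    sex: str  # "male" | "female"
    age: float


@dataclass(frozen=True)
class RiskLabels:
    bp_abnormal: bool
    lipids_abnormal: bool
    obesity: bool
    anyRISKoutof9: bool


def clinical_labels(panel: LabPanel) -> RiskLabels:
    """Evaluate the nine threshold criteria; boundary values are not at risk."""
    for fieldname in _REQUIRED:
        v = getattr(panel, fieldname)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing laboratory measurement: {fieldname}")
    bp = panel.sbp > 140 or panel.dbp > 90
    lipids = (
        panel.triglycerides > 2.3
        or panel.total_cholesterol > 6.2
        or panel.hdl < 1
        or panel.ldl > 4.1
    )
    waist_limit = 100 if panel.sex == "male" else 90
    obese = panel.waist > waist_limit or panel.bmi > 27.5
    glucose = panel.glucose > 6
    return RiskLabels(
        bp_abnormal=bool(bp),
        lipids_abnormal=bool(lipids),
        obesity=bool(obese),
        anyRISKoutof9=bool(bp or lipids or obese or glucose),
    )


def clinical_labels_frame(labs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized clinical labels for a labs table (one row per participant)."""
    out = pd.DataFrame({"participant_id": labs["participant_id"]})
    rows = []
    for row in labs.itertuples(index=False):
        panel = LabPanel(
            sbp=row.sbp,
            dbp=row.dbp,
            triglycerides=row.triglycerides,
            total_cholesterol=row.total_cholesterol,
            hdl=row.hdl,
            ldl=row.ldl,
            glucose=row.glucose,
            waist=row.waist,
            bmi=row.bmi,
            sex=row.sex,
            age=row.age,
        )
        lab = clinical_labels(panel)
        rows.append([lab.bp_abnormal, lab.lipids_abnormal, lab.obesity, lab.anyRISKoutof9])
    out[list(CLINICAL_TARGETS)] = rows
    return out


def _nearest_rank_percentile(scores: np.ndarray, pct: float) -> float:
    """Inclusive nearest-rank percentile: smallest value with >= pct% at or below."""
    srt = np.sort(scores)
    n = srt.size
    rank = int(np.ceil(pct / 100 * n))
    rank = min(max(rank, 1), n)
    return float(srt[rank - 1])


def genomic_labels(
    pgs: pd.DataFrame,
    pgs_map: pd.DataFrame,
    cutoff: int = 90,
) -> pd.DataFrame:
    """High-genomic-risk flags per target at the given percentile cut-off.

    ``pgs`` has columns ``participant_id, pgs_id, score``; ``pgs_map`` has
    ``pgs_id, target, risk_direction`` with target in {lipids, bp, obesity}
    and risk_direction in {high_score_risky, low_score_risky}.  ``cutoff`` is
    the upper percentile (90 means top/bottom decile, i.e. the 90/10 rule).
    A score lying exactly on the empirical percentile is inside the tail.

    The result carries ``include_age=False`` in ``DataFrame.attrs`` as a
    reminder that age must not enter models of these targets.
    """
    if cutoff not in (80, 85, 90):
        raise ValueError("supported cut-offs: 90 (90/10), 85 (85/15), 80 (80/20)")
    known = set(pgs_map["pgs_id"])
    unknown = set(pgs["pgs_id"]) - known
    if unknown:
        raise ValueError(f"unknown pgs_id(s): {sorted(unknown)}")
    direction = dict(zip(pgs_map["pgs_id"], pgs_map["risk_direction"]))
    target_of = dict(zip(pgs_map["pgs_id"], pgs_map["target"]))

    ids = pd.Index(sorted(pgs["participant_id"].unique()), name="participant_id")
    flags = pd.DataFrame(False, index=ids, columns=list(GENOMIC_TARGETS))
    for pgs_id, grp in pgs.groupby("pgs_id"):
        scores = grp["score"].to_numpy(dtype=float)
        if scores.size < 10:
            raise ValueError(
                f"{pgs_id}: need >= 10 scored participants for percentile labels"
            )
        if direction[pgs_id] == "high_score_risky":
            thr = _nearest_rank_percentile(scores, cutoff)
            risky = grp.loc[grp["score"] >= thr, "participant_id"]
        else:
            thr = _nearest_rank_percentile(scores, 100 - cutoff)
            risky = grp.loc[grp["score"] <= thr, "participant_id"]
        col = {"lipids": "genomic_lipids", "bp": "genomic_bp", "obesity": "genomic_obesity"}[
            target_of[pgs_id]
        ]
        flags.loc[flags.index.isin(risky), col] = True
    out = flags.reset_index()
    out.attrs["include_age"] = False
    return out
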