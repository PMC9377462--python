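# wearphen

Activity-contextualized, high-resolution digital phenotypes from consumer
wearable recordings, and their associations with clinical and genomic
cardiometabolic risk markers.

Consumer wrist devices record heart rate and step counts continuously in
free-living conditions, but the recordings are messy: heart rate arrives at
1-minute intervals or in irregular 5/10/15-second bursts, steps at 1- or
15-minute intervals, and roughly an hour and a half per day of heart-rate
data is simply missing. `wearphen` is for biostatisticians and digital-health
researchers who want to go beyond daily summary statistics and ask whether
the *dynamics* of heart rate — separately during sleep, sedentary time, and
activity — carry information about cardiometabolic risk.

## What it computes

1. **Standardized annotation.** Streams are regularized to a 1-minute grid;
   only days with ≥ 20 hours of jointly valid heart-rate and step data are
   kept. Each valid minute is labeled *sleep* (device sleep log), *sedentary*
   (zero steps), or *active* (the rest), with sleep taking precedence.

2. **High-resolution features.** For each state, the longest uninterrupted
   heart-rate run is truncated to a standard length — first 20 min (active),
   60 min (sedentary), 300 min (sleep) — and summarized by the 22 canonical
   time-series characteristics (distribution shape, extreme-event timing,
   symbolic transitions, linear/nonlinear autocorrelation, successive
   differences, fluctuation analysis), implemented here from scratch in NumPy
   and tested for 1e-6 agreement with the published reference implementation.
   Up to 3 × 22 = 66 features per participant, plus wearable-derived resting
   heart rate (mean bpm over minutes with ≤ 100 steps) and 10 summary
   statistics including sinusoidally encoded sleep/wake times.

3. **Risk-marker association.** Binary clinical targets come from nine
   laboratory thresholds (blood pressure, lipids, glucose, obesity, and an
   omnibus `anyRISKoutof9`); genomic targets flag membership in the risk tail
   of any relevant polygenic score (90/10, 85/15, or 80/20 cut-offs). Each
   feature set (seven model types from `Baseline` = age+gender up to
   `Unified`) is evaluated by class-balanced random forests: every tree's
   bootstrap draws floor(0.8·n_minority) minority samples and as many
   majority samples, and the out-of-bag (OOB) probabilities are scored by

       BrierScore(M) = Σᵢ (pᵢ − oᵢ)² / N

   over many independently seeded forests. Model pairs are compared with
   two-tailed Welch *t* tests under Benjamini–Hochberg FDR control, variable
   importance by permutation mean decrease in accuracy, and individual
   predictions are profiled with sampling-based Shapley values (top-5
   features by |Φ|).

4. **Synthetic cohorts.** Because real cohort data of this kind is not
   redistributable, `wearphen.simulate` generates device-realistic cohorts —
   burst sampling, 15-minute step aggregation, ~95 missing heart-rate
   minutes per day, nightly sleep logs — with *plantable* state-specific
   dynamics effects linked to risk labels, so the entire pipeline is testable
   end to end.

## Worked example

```python
from wearphen import (SimConfig, simulate_cohort, build_feature_table,
                      complete_cases, clinical_labels_frame, RiskModel, compare_models)

config = SimConfig(
    n_participants=200, seed=7,
    effect_plan={("SEDENTARY", "amplitude"): 1.0},   # plant a sedentary-dynamics effect
)
cohort = simulate_cohort(config)
features = complete_cases(
    build_feature_table(cohort.recordings, cohort.labs[["participant_id", "age", "sex"]])
)
table = features.merge(clinical_labels_frame(cohort.labs), on="participant_id")

y = table["anyRISKoutof9"].astype(int)
baseline = RiskModel(table, y, spec="Baseline", target="anyRISKoutof9").fit(n_replicates=20, seed=1)
seden = RiskModel(table, y, spec="HighRes.SedenSeg", target="anyRISKoutof9").fit(n_replicates=20, seed=1)
print(seden.summary())
print(compare_models([baseline, seden])[["model_a", "model_b", "mean_brier_a",
      "mean_brier_b", "improvement_pct", "q_value"]].to_string(index=False))
```

prints

```
Risk model results: HighRes.SedenSeg -> anyRISKoutof9
======================================================
participants:        200
positives:           105
features:            24
trees per forest:    500
replicates:          20
OOB Brier (mean):    0.1298
OOB Brier (SD):      1.41e-03

 model_a          model_b  mean_brier_a  mean_brier_b  improvement_pct      q_value
Baseline HighRes.SedenSeg      0.256435      0.129837        49.368331 8.386741e-44
```

The age+gender baseline sits at the uninformative level (≈ 0.25: age and sex
are independent of risk in this cohort), while the 22 sedentary-segment
dynamics features recover the planted effect, halving the Brier score with
overwhelming evidence in the Welch/BH comparison.

The same stages are scriptable from a shell:

```bash
wearphen simulate --n 200 --seed 7 --out simdata/
wearphen features --hr simdata/heart_rate.csv --steps simdata/steps.csv \
    --sleep simdata/sleep_log.csv --demographics simdata/labs.csv --out features.csv
wearphen label --labs simdata/labs.csv --pgs simdata/pgs.csv \
    --pgs-map simdata/pgs_map.csv --out labels.csv
wearphen train --features features.csv --labels labels.csv \
    --target anyRISKoutof9 --models Baseline,HighRes.SedenSeg --out eval/
```

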