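# Methods

This note documents the models, conventions, and parameter choices behind
`wearphen`, and states what the synthetic cohorts do and do not emulate.

## Annotation model

Raw streams are regularized to one record per calendar minute. Within-minute
heart-rate aggregation is the arithmetic mean of all samples falling in
[minute, minute+1) — an order-free choice consistent with resampling burst
recordings. Step records at 1-minute resolution map directly; coarser
intervals (15 min) are allocated uniformly across their covered minutes with
the integer remainder given to the earliest minutes, so step totals are
conserved exactly and stretches of truly zero steps are preserved whenever a
whole coarse interval is zero. Days are local calendar days (minutes indexed
0..1439); a *valid day* has at least 1200 minutes (20 h) with both streams
present, boundary inclusive. Minutes missing either stream carry a null
state and are excluded from all statistics.

States are assigned with precedence sleep > sedentary > active: any minute
inside a device sleep-log interval is sleep regardless of steps; remaining
minutes with a zero step count are sedentary; everything else is active.

An *uninterrupted run* is a maximal block of consecutive minutes sharing one
state with a valid heart-rate value at every minute; a single missing minute
breaks the run. Runs may cross midnight when the record is contiguous.
Standardized segments truncate the longest run per state to its first L
minutes, L = 20 (active), 60 (sedentary), 300 (sleep); a state whose longest
run is shorter than L yields no segment for that participant. Ties among
equally long runs resolve to the earliest start, making extraction
deterministic and invariant to data after the chosen run.

## The 22 time-series characteristics

Each standardized segment is z-scored (sample n−1 standard deviation) and
passed through the 22 canonical characteristics. The implementation is a
from-scratch NumPy port that reproduces the published reference
implementation to 1e-6 relative tolerance on 100 random series of lengths
50–500 (frozen reference values in `tests/data/catch22_reference.csv`,
regenerable via `scripts/make_catch22_reference.py`). The conventions that
matter numerically:

- **Autocorrelation** uses the biased FFT estimator (series zero-padded to
  twice the next power of two, normalized at lag 0); the first-zero lag and
  the interpolated 1/e crossing derive from it. The Gaussian auto-mutual
  information instead uses Pearson correlations of the truncated, lagged
  subsequences (each re-centered), matching the reference.
- **Histograms** span [min, max] with equal-width bins; a value lands in bin
  ⌊(x−min)/width⌋, clamped to the top bin. Ties in the modal bin count
  *average the tied bin centers*.
- **Symbolization** uses plotting-position quantiles (rank − ½)/n with
  linear interpolation and edge clamping, three equiprobable symbols.
- **Spectral summaries** come from a single rectangular-window Welch
  periodogram (NFFT = next power of two, one-sided, interior bins doubled);
  the centroid is the first angular frequency whose cumulative spectrum
  passes half the total, and the low-frequency area integrates the lowest
  fifth of the frequency bins.
- **Fluctuation analysis** (detrended-fluctuation and rescaled-range
  variants) evaluates ~50 log-spaced window sizes from 5 to half the series
  length and reports the proportion of scales assigned to the first segment
  of the best two-piece log–log linear fit (minimum six points per piece).
  When fewer than 12 distinct window sizes exist — always the case for
  20-point active segments — the feature is identically 0. This is a
  structural degeneracy, not a failure, and downstream correlation tables
  report NA for features that are constant within a state.

**Fallback policy.** Constant segments, segments shorter than a feature's
minimum supported length, and non-finite intermediate results all map to
0.0 with a per-feature degeneracy flag. Downstream forests therefore always
receive finite design matrices, and the uniformly zero fluctuation features
on active segments arise naturally from the definition above.

**Known numerical sensitivity.** For heavily quantized inputs (many exactly
equal values), histogram-mode features can flip bins under one-ulp changes
in the mean/variance accumulation order; this is inherent to the feature
definition (the reference implementation shows the same sensitivity across
compilers) and does not affect continuous-valued inputs.

## Summary features

Resting heart rate is the mean bpm over valid-day minutes with a valid step
count ≤ 100 (boundary inclusive). The 10-feature summary block comprises
mean daily active/sedentary/sleep minutes, mean daily steps (valid days
only), sine and cosine encodings of the average wake and sleep-onset times,
mean sleep-episode length, and episodes per day. Wake and onset times come
from each day's main (longest) logged episode and are averaged *circularly*
(vector mean on the 24-hour circle) before encoding as
(sin 2πt/24, cos 2πt/24), so times straddling midnight average to midnight
rather than noon. Episode statistics cover all logged intervals starting on
valid days; episodes per day averages over days with at least one episode.
Participants without usable sleep logs carry NaN in the sleep-derived fields
(durations and steps are still computed), and such rows are excluded from
modeling by `complete_cases`.

## Risk labels

Clinical thresholds are strict inequalities: SBP > 140, DBP > 90 mm Hg;
triglycerides > 2.3, total cholesterol > 6.2, HDL < 1, LDL > 4.1,
glucose > 6 mmol/L; waist > 100 cm (male) / > 90 cm (female); BMI > 27.5.
Boundary values are not at risk. `bp_abnormal` = I–II, `lipids_abnormal` =
III–VI, `obesity` = VIII–IX, `anyRISKoutof9` = any of I–IX.

Genomic labels use inclusive nearest-rank percentiles: at the 90/10 cut-off
a score is in the risk tail when it is ≥ the empirical 90th percentile
(high-score-risky direction) or ≤ the 10th (low-score-risky); a target's
label is the OR over its scores (14 lipid, 2 blood-pressure, 1 obesity).
Relaxing the cut-off (90/10 → 85/15 → 80/20) is monotone: labels can only
switch from false to true. Because genomic risk is independent of age, the
label table carries an `include_age=False` flag and model assembly drops age
for genomic targets.

## Balanced random forests and model comparison

Each (feature set, target) pairing is evaluated by an ensemble of CART trees
with stratified balanced bootstraps: floor(0.8·n_minority) minority draws
and equally many majority draws per tree, with replacement. Defaults: 500
trees per forest, √p candidate features per split, minimum leaf size 25.
Replicate r of an evaluation uses seed base+r, yielding (by default 200)
independent OOB Brier scores per model.

**OOB probability convention.** The OOB probability for a participant
averages the positive-class *leaf probabilities* of the trees whose
bootstrap excluded them, rather than counting 0/1 votes. This choice is
deliberate: with fully grown trees and vote counting, a small feature set
(e.g. age+gender) produces strongly correlated, confident votes even on
pure-noise labels, inflating the null Brier score far above the
uninformative 0.25 level (≈0.38 measured here, and ≈0.29 even for the R
randomForest implementation of the same protocol). Averaged leaf
probabilities with a 25-sample minimum leaf keep every model type's null
Brier within a few thousandths of 0.25 while leaving planted effects easy
to recover (a sedentary-dynamics effect at n = 400 drives the sedentary
model to ≈0.13 against a 0.25 baseline). Vote counting remains available
via `BalancedRandomForest(probability_mode="vote")`.

Pairwise model comparison applies two-tailed Welch *t* tests to the
replicate Brier-score vectors and controls the false discovery rate with
Benjamini–Hochberg within each target; relative improvement is
100·(B_ref − B_model)/B_ref. Variable importance is the unscaled permutation
mean decrease in OOB accuracy per tree, averaged over trees and replicates;
top-k rankings break ties lexicographically.

## Shapley profiling

Per-participant attributions use the sampling-permutation estimator: for
each random feature ordering, features switch one by one from a background
sample's values to the participant's values, and the successive changes in
the mean predicted probability accumulate into Φ. The telescoping
construction makes efficiency (baseline + ΣΦ = prediction) exact for every
permutation; permutations only reduce the variance of the per-feature split.
Defaults: 100-row background, 100–200 permutations; top-5 features by |Φ|,
ties by name.

## Synthetic cohorts

The generator emulates the *recording* irregularities of consumer-device
cohorts: 3–5 days per participant; heart rate at 1-minute resolution or as
5/10/15-second bursts (per-participant dialect); steps at 1-minute or
15-minute resolution; daily missing heart-rate totals drawn from a truncated
normal with mean 94.9 and SD 85.8 minutes (capped at 200 so every generated
day stays valid), placed as 1–3 contiguous afternoon/evening stretches; one
main nocturnal sleep episode per night plus occasional naps, all logged.
Each day guarantees one ≥25-minute active bout, one ≥75-minute sedentary
stretch aligned to the 15-minute step grid, and ≥380 sleep minutes, so all
three standardized segments are derivable for every participant under
defaults.

Heart rate is a state-switching AR(1) (mean reversion φ = 0.85; levels
55/68/95 bpm and noise 1.2/2.2/4.5 bpm for sleep/sedentary/active). The
*effect plan* maps (state, property) to an effect size applied only to
at-risk participants: `amplitude` adds half-wave-rectified oscillations
(episodic upward surges, period 18 min, 8 bpm per unit effect) and
`spikiness` adds sporadic exponential spikes. Surges are rectified rather
than sinusoidal on purpose: a symmetric oscillation moves the z-scored
histogram mode to +A or −A with a random sign per participant, which leaves
group means unshifted; rectified surges skew the distribution consistently,
so the planted effect is detectable by a plain two-sample *t* test on the
sedentary histogram-mode feature as well as by the forests.

Laboratory values are drawn so the clinical threshold predicates reproduce
the intended risk label exactly (positives exceed 1–3 randomly chosen
criteria; negatives are capped below every threshold), and 17 polygenic
scores are standard normal (one lipid score runs in the protective
direction to exercise both tail rules). Age and sex are independent of the
risk label, so baseline models are uninformative by construction.

**What the generator does not emulate** — circadian drift within states,
heart-rate/step cross-correlation beyond the state schedule, device-specific
quantization artifacts, wear-time gaps longer than a few hours, label noise
in the laboratory panel, and realistic linkage disequilibrium structure
among polygenic scores. Passing tests therefore demonstrate that the
pipeline recovers the *kinds* of state-specific dynamical signals it was
designed for under realistic recording irregularities, not that any specific
cohort-level effect size will transfer to real populations.

## Problem sizes used in tests

The test suite and acceptance checks run the stochastic analyses at sizes
chosen to make their statistical claims decisive on a single CPU: 400
participants / 50 replicates / 300 trees for planted-effect recovery, 300
participants / 20 replicates per model type for null calibration, 200
participants for recording-realism statistics, and 100 reference series for
feature-set equivalence. Larger cohorts change none of the contracts; the
generator scales linearly.

## Known limitations

- The composition of the 10-feature summary block follows the described
  construction (3 durations, daily steps, 4 sinusoidal components, 2
  episode statistics); alternative compositions are configurable but not
  implemented as presets.
- Percentile and quantile conventions (nearest-rank inclusive tails,
  plotting-position symbolization quantiles) are fixed to the documented
  choices; cohorts with heavy score ties may want explicit tie policies.
- The forests use a single hyperparameter setting; no tuning is performed,
  by design, since the protocol's purpose is comparative evaluation of
  feature sets under identical conditions.
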