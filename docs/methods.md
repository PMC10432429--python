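# Methods

## Problem and day indexing

The unit of analysis is the patient-day. POD 0 is the day of surgery;
monitoring covers PODs 1..21 (configurable via `monitoring_days`). Each
monitored day receives exactly one ground-truth label:

* **abnormal** — the day falls in the 1–2 days leading up to a reported
  postoperative event (an abnormal symptom or a confirmed NSQIP
  complication; both generate windows identically, the Clavien-Dindo grade
  and NSQIP flag only describe the event);
* **excluded** — the event day itself, which is never used for training or
  testing (the goal is detection *before* the report, and the day of the
  report is contaminated by the event itself);
* **normal** — everything else.

Boundary rules: an event on POD 2 yields one abnormal day (POD 1); an event
on POD 1 yields none. When rules collide (a day is both an event day and
inside another event's window), exclusion wins — the event day is
unconditionally withheld. Days after an event revert to normal unless a
later event's window captures them. Each event owns its window even when the
same symptom recurs; duplicate records of the same patient/POD/category
collapse with a warning. These precedence choices are configurable in
principle but are the fixed defaults.

## Features

The canonical feature set has 74 columns: 14 activity and 4 sleep fields
passed through from the device's daily export, 5 heart-rate features, 8
demographic columns (age, weight, height, a female indicator, and
race/ethnicity one-hot expanded into 4 indicators), 8 clinical-course
features, and 35 temporal variants — five operators applied to seven flagged
features (total steps, total distance, calories, resting HR, minutes asleep,
minutes in bed, minutes restless):

* `delta` = v[pod] − v[pod−1];
* `roll3_diff` = v[pod] − mean of the values present among PODs pod−3..pod−1
  (the current day is excluded; the window is calendar PODs, not the last
  three *observed* days, so a data gap simply shrinks the window);
* `roll3_pct` = 100·roll3_diff / rolling mean (missing when the mean is 0);
* `max_diff` / `min_diff` = v[pod] minus the maximum / minimum of all
  previous present values.

Any quantity with no qualifying prior data is missing, not zero. Whether the
named enumeration of base features plus variants exactly matches a
"75-feature" accounting depends on how categorical encodings are counted;
this package fixes the canonical set at the 74 columns above and treats it as
the single source of truth (`postopfit.FEATURE_COLUMNS`, which also defines
the deterministic order used by correlation pruning).

Heart-rate statistics (mean, sample SD with the n−1 denominator, min, max)
are recomputed from the minute stream over worn minutes only; a day with no
worn minutes has all four missing, and a single worn minute has a defined
mean but missing SD. Resting HR, distances, calories and sleep staging are
device-proprietary quantities: they are consumed from the daily summary and
never recomputed from raw signals.

Clinical features use only events strictly before the query day (no leakage
of the event being predicted). `days_post_symptom`/`days_post_complication`
use the days-since-surgery value as the no-prior-event fallback — an upper
bound that keeps the feature numeric without a magic sentinel. The discharge
indicator derives from ceil(length of stay); an explicit `discharge_pod`
column in the roster overrides it.

**Wear time.** A minute counts as worn iff an HR sample was recorded and
positive; wear compliance is worn hours within 06:00–24:00 (so at most 18 h).
A day enters the modeling table iff *any* data were recorded that day; the
10 h compliance filter is a sensitivity analysis, not a default. Days of
sufficient wear adjacent to a filtered-out day keep their original labels.

## Classifier

A balanced random forest: `n_trees` (default 100) CART trees, each fit on an
independent balanced bootstrap — exactly `n_minority` draws with replacement
from *each* class — with `sqrt(p)` candidate features per split and unlimited
depth. These hyper-parameter defaults are standard practice for this
estimator and are all overridable; none is tuned. The day score is the
fraction of trees voting abnormal; the abnormal call uses score ≥ 0.5, with
the tie counting as abnormal (sensitivity is worth more than specificity in a
post-discharge safety screen). Trees come from scikit-learn; the balanced
bootstrap, ensemble voting and importance averaging are implemented here.
The `tree_factory` seam accepts any sklearn-style estimator constructor for
plugging in alternative base learners; no alternatives ship with the
package.

**Preprocessing.** Features with pairwise-complete Pearson |r| > 0.95 to an
already-retained feature are dropped by a greedy scan in canonical column
order (deterministic; zero-variance features have undefined correlation and
are retained and flagged). Missing cells are imputed with the patient's own
mean of that feature over their monitoring period; a patient who never
observed a feature falls back to the training-split grand mean; a feature
observed nowhere is dropped with a warning.

**Cross-validation.** Leave-one-subject-out: one fold per patient, all of a
patient's days held out together (days within a patient are correlated, so a
day-level split would leak). By default pruning and imputation are re-fit
inside each fold from the training patients only; `paper_faithful=True` fits
them once globally before splitting. The difference is immaterial on the
synthetic cohorts but the leakage-free variant is the default on principle;
held-out days are imputed from the held-out patient's *own* means (their own
past data, available at prediction time), with training grand means as
fallback. Per-fold seeds derive from a single `SeedSequence`, so a run is
reproducible to full precision from one integer.

Separate models are fit for the complicated and simple appendicitis groups
(the two diseases have different recovery trajectories); the pooled model is
sensitivity analysis 4, not the default.

## Evaluation

AUROC and AUPRC are computed on the pooled out-of-fold scores rather than
averaged per fold, because a single held-out patient frequently has only one
class and per-fold areas would be undefined; a per-fold averaging mode is not
asserted as equivalent. AUROC is the Mann–Whitney pairwise concordance (ties
= 1/2); AUPRC is non-interpolated average precision, reported next to its
prevalence baseline (the AUPRC of a random scorer equals the positive
prevalence, exactly `n_abnormal / n_included_days`). Confidence intervals
are 90% percentile bootstrap over **patients** (resample patients with
replacement, pool their days; 1000 reps by default), which respects
within-patient correlation; degenerate single-class resamples are skipped,
and the interval is reported missing when more than half degenerate.

Event-level detection: an event on POD k is detected at d₋2 (d₋1) iff the
model predicted abnormal on POD k−2 (k−1) *and* that day exists in the
modeling table. Denominators follow the event's position: d₋2 excludes
events on POD ≤ 2, d₋1 excludes POD-1 events, and d_ANY counts events with
at least one existing labeled prior day. An event with no existing prior day
(e.g. on POD 1, or with both prior days missing/excluded) is excluded from
all three denominators — the alternative of counting such events as
undetected is a stricter convention; the counts needed to recompute either
way (numerators and denominators) are reported alongside the percentages.
Missed events are listed with their Clavien-Dindo grade. When pre-event
windows of two events overlap, each event still owns its own window for
detection accounting.

Feature importance is mean Gini importance per feature across folds
(features a fold pruned contribute 0), normalized to sum to 1 and ranked.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline assumes:

| parameter | complicated | simple |
|---|---|---|
| patients | 85 | 76 |
| expected events/patient (Poisson) | 41/85 | 10/76 |
| Clavien grade mix | I:22, II:14, III:5 (of 41) | I:9, III:1 (of 10) |
| daily wear hours (mean ± SD, clipped 2–17.5) | 12.8 ± 6.0 | 12.3 ± 6.3 |
| length of stay, days (mean ± SD) | 4.0 ± 2.6 | 0.9 ± 0.7 |
| Inspire HR fraction | 69/85 | 43/76 |
| recovery ramp midpoint / scale (PODs) | 9 / 3 | 5 / 2 |

Expected daily steps follow a logistic ramp from a nadir (20% of an
age-scaled plateau, lognormal across patients around 9,000 steps) toward
the plateau, slower for the complicated group, with lognormal day-to-day
noise (CV 0.25). Worn minutes form a contiguous daytime block with random
gaps (contiguous overnight non-wear); non-worn minutes have no HR sample.
Within worn minutes, ~15% are active with Poisson step bursts sized to hit
the day's expected total; minute HR is an age-dependent baseline plus an
activity term and Gaussian noise. Daily summaries are recomputed from the
(possibly perturbed) minute stream: intensity minutes partition worn minutes
at 67 / 30 / 1 steps-per-minute thresholds, distances use a height-scaled
stride, energy is BMR plus a per-step increment, resting HR is a low
quantile of worn HR, and sleep comes from a simple Gaussian model
(asleep ≤ in-bed by construction). 3% of days drop out entirely (no data);
10% of summary rows lack sleep fields.

The pre-event perturbation — the signal the classifier must recover — scales
minute steps by (1 − suppression) and offsets worn-minute HR on PODs k−2 and
k−1. Its default magnitude (50% suppression, +15 bpm) is deliberately strong:
a signal-recovery regime for validating the pipeline, not a claimed clinical
effect size (no quantitative pre-event effect is established in the
literature; the parameter is free). Event timing is uniform over the
monitoring window by default so that, with zero injected effect, day labels
are independent of the day-level features and the pipeline's null AUROC sits
at chance; an early-skewed (truncated-geometric) timing option exists but
deliberately confounds labels with the recovery ramp.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physiologically validated HR dynamics or circadian
structure beyond wear gaps, device firmware idiosyncrasies, reporting
behavior (recall bias, survey timing), correlation between wear compliance
and illness severity, and realistic (weak, heterogeneous) pre-event effect
sizes. Performance numbers on synthetic cohorts validate the machinery, not
clinical performance.

## Numerical choices and degenerate inputs

* Rolling means use direct 3-term window sums (not cumulative-sum
  differences), avoiding catastrophic cancellation at mixed magnitudes.
* `roll3_pct` is missing when the rolling mean is exactly 0.
* Fewer than 2 abnormal training days → the forest refuses to fit; `run_all`
  skips that group with a diagnostic instead of aborting.
* A sensitivity variant leaving < 2 patients or a single class aborts with a
  diagnostic.
* A day of recorded zero HR is a *worn-off* day with data (`any_data` true,
  wear 0 h); a day with no rows anywhere is omitted from the modeling table.
* CSV outputs use fixed float formatting and `\n` line endings so
  fixed-seed runs are byte-identical (digest-verified in the run manifest).

## Problem sizes used by the test suite and acceptance script

Unit tests run on small cohorts (≤ 10 patients). The signal-recovery,
ablation and null checks run at the full default scale (85 + 76 patients,
21 days); the null check averages pooled AUROC over 10 generator seeds, the
scale at which patient-level clustering still leaves visible seed-to-seed
spread (individual seeds scatter roughly ±0.1 around chance). The acceptance
script runs the complete two-group pipeline once at the default scale with
200 bootstrap CI replicates.
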