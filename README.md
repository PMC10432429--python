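# postopfit

Early detection of abnormal postoperative recovery from consumer-wearable
data after pediatric appendectomy.

When children go home after an appendectomy, caregivers mostly judge recovery
subjectively. A wrist-worn consumer device (Fitbit-class) records minute-level
heart rate and steps plus daily activity/sleep summaries, and the 1–2 days
before an abnormal symptom or confirmed complication often carry a detectable
change in those signals. `postopfit` implements the full analysis pipeline
for this problem, for biostatisticians and digital-health researchers:

1. **Synthetic cohort generation** — a post-appendectomy cohort (two severity
   groups, *complicated* and *simple* appendicitis) with 21-day monitoring,
   minute-level HR/step streams with realistic non-wear gaps, daily
   activity/sleep summaries, and sparse postoperative events graded on the
   Clavien-Dindo scale. A configurable perturbation (step suppression, HR
   elevation) is injected on the 1–2 days before each event.
2. **Feature engineering** — per patient-day vectors: activity and sleep
   summary fields, daily HR statistics over worn minutes, demographics,
   clinical-course features, and five temporal variants (Δ previous day,
   δ 3-day rolling average, % change from rolling average, Μ difference from
   the running maximum, μ difference from the running minimum) for seven
   flagged features. Wear time is inferred from HR (zero/absent = not worn)
   within waking hours 06:00–24:00.
3. **Ground-truth labeling** — for an event on POD *k* (POD 0 = day of
   surgery), PODs *k−2* and *k−1* are *abnormal*, POD *k* is *excluded* from
   training/testing, all other days *normal*.
4. **Classification** — a balanced random forest: each of *T* trees is fit on
   a bootstrap that under-samples the majority class (with replacement) to
   the minority size, so every tree sees exact class balance. The day score
   is the fraction of trees voting abnormal. Evaluation uses
   leave-one-subject-out cross-validation (all days of one patient held out
   per fold), with correlation pruning (pairwise Pearson |r| > 0.95) and
   patient-mean imputation re-fit inside each fold.
5. **Evaluation** — pooled confusion matrix, AUROC/AUPRC with patient-level
   bootstrap 90% CIs, the prevalence baseline (a random scorer's AUPRC equals
   the abnormal-day prevalence), event-level early-detection rates
   (d₋₂ / d₋₁ / d_ANY), averaged Gini feature importance, and four
   sensitivity analyses (no wearable features; ≥10 h wear-time filter;
   single device generation; pooled severity groups).

## Worked example

```python
import postopfit as pf

cohort = pf.generate_cohort(pf.CohortConfig(seed=1))
features, wear = pf.build_feature_matrix(cohort)
labels = pf.label_days(cohort.events, cohort.patients, cohort.monitoring_days)
dataset, counts = pf.dataset_assembly(features, wear, labels, cohort.patients)

sub = dataset[dataset["group"] == "complicated"]
events = cohort.events[cohort.events["patient_id"].isin(set(sub["patient_id"]))]
report, predictions = pf.run_group_pipeline(
    sub, events, pf.ModelParams(seed=1), group="complicated", ci_reps=200)
print(counts["complicated"])
print(round(report.auroc, 3), report.d_any_counts, round(report.d_any_pct, 1))
```

prints

```
{'n_days': 1704, 'n_abnormal': 53, 'n_patients': 85}
0.998 (26, 29) 89.7
```

i.e. the complicated group contributed 1,704 included patient-days of which
53 are abnormal (the 1–2 days before an event); under leave-one-subject-out
cross-validation the pooled AUROC is 0.998, and 26 of the 29 events with at
least one labeled prior day were flagged on one of the two days before they
were reported (d_ANY = 89.7%). The signal is this strong because the default
generator injects a 50% step suppression and +15 bpm HR elevation before each
event; set `pre_event_effect=pf.PreEventEffect(0.0, 0.0)` for a null cohort,
where the AUROC drops to chance.

The same pipeline runs from the shell:

```bash
postopfit simulate --out data/ --seed 1
postopfit run-all --out run/ --seed 1
postopfit sensitivity --data data/ --variant no_fitbit --out run/ --seed 1
```

## Data dialect

`simulate` writes, and `features`/`label`/`run-all --data` read, five CSVs
(ISO-8601 minute-resolution local timestamps):

| file | columns |
|---|---|
| `patients.csv` | `patient_id,group,age_years,sex,race_ethnicity,weight_kg,height_cm,device,length_of_stay_days,monitoring_days,surgery_date` |
| `events.csv` | `patient_id,pod,category,clavien_grade,nsqip` |
| `minute_hr.csv` | `patient_id,timestamp,hr_bpm` (one row per recorded minute; 0 = worn-off) |
| `minute_steps.csv` | `patient_id,timestamp,steps` |
| `daily_summary.csv` | `patient_id,pod` plus the daily activity/sleep fields (total steps, distances, intensity minutes, calories, resting HR, sleep minutes/records); any field may be blank |

User-supplied exports with these headers drop straight into the pipeline;
`postopfit validate --data DIR` checks them first.

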