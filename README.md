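# perimob

Peri-operative mobility analysis from smartphone daily step counts.

Spine surgery for degenerative stenosis or spondylolisthesis usually restores
a patient's mobility, but a substantial minority later lose the function they
regained — adjacent segment disease and progressing spondylosis can erode a
successful index surgery months after full recovery. Smartphones record a
continuous, objective proxy for that function: steps per day across the whole
peri-operative window. `perimob` implements the analysis pipeline that turns
those raw exports into an early-warning classifier for **secondary
post-operative functional decline**, and ships a ground-truthed synthetic
cohort generator so every stage can be validated without patient data.

The pipeline, for each patient with a daily step series spanning two years
before through two years after surgery:

1. **Normalize & smooth.** Steps are divided by the mean of the *baseline
   year* (days −730 … −366 before surgery), so activity is expressed in units
   of the patient's own baseline; the series is then smoothed with a
   centered 14-day sliding window (missing days shrink the denominator, they
   are never imputed as zero).
2. **Segment into six temporal epochs** with a deterministic
   threshold-plus-hysteresis state machine: (1) pre-operative baseline,
   (2) acute pre-operative decline, (3) spontaneous recovery, (4) acute
   post-operative recovery, (5) fully recovered at or above baseline,
   (6) secondary decline after full recovery. Detected boundaries are refined
   to the nearest shape feature (local extremum or slope kink) of the
   smoothed curve.
3. **Call the outcome.** A patient has a secondary decline when mean
   steps-per-day in a trailing window of epoch 6 sits **≥ 0.25 baseline
   standard deviations** below the epoch-5 mean (inclusive threshold, in raw
   steps/day units). No epoch 5 ⇒ no decline, by definition.
4. **Build features**: per-epoch cumulative durations, 1st derivatives
   (least-squares slope of smoothed activity vs day) and 2nd derivatives
   (slope of the first differences), plus age at surgery and BMI. The
   default `pre_recovery` leakage policy admits epochs 1–4 only; the
   `with_recovery` policy adds epoch 5; epoch-6 information is never a
   predictor.
5. **Benchmark three classifiers** — L2-regularized logistic regression,
   random forest, gradient-boosted trees — on a single stratified 4:1
   train/validation split, reporting accuracy, sensitivity, specificity,
   PPV, NPV and the AUROC (the Mann–Whitney probability that a random
   positive outscores a random negative, ties half-credited), with feature
   importances for the tree models.

## Worked example

Simulate a 400-patient cohort under favourable (low-noise) conditions,
run the full pipeline, and benchmark the three classifiers against the
generative decline labels:

```python
from perimob import SplitSpec, split_cohort, train_classifier, evaluate_model
from perimob.pipeline import analyze_cohort, duration_table
from perimob.simulate import CohortConfig

cohort = analyze_cohort(400, CohortConfig.low_noise(), seed=11, label_source="truth")
print(f"patients: {len(cohort.X)}  decliners: {int(cohort.y.sum())} "
      f"({100*cohort.y.mean():.1f}%)")

X_tr, X_te, y_tr, y_te = split_cohort(cohort.X, cohort.y, SplitSpec(seed=0))
for kind in ("logistic_regression", "random_forest", "gradient_boosted_trees"):
    ev = evaluate_model(train_classifier(X_tr, y_tr, kind, seed=0), X_te, y_te)
    print(f"{kind:24s} accuracy={100*ev.metrics['accuracy']:.1f}% "
          f"sens={100*ev.metrics['sensitivity']:.1f}% "
          f"spec={100*ev.metrics['specificity']:.1f}% AUC={ev.auroc:.2f}")
```

prints

```
patients: 400  decliners: 152 (38.0%)
logistic_regression      accuracy=88.8% sens=80.0% spec=94.0% AUC=0.95
random_forest            accuracy=86.2% sens=83.3% spec=88.0% AUC=0.93
gradient_boosted_trees   accuracy=86.2% sens=83.3% spec=88.0% AUC=0.93
```

Thirty-eight percent of the generated patients secondarily declined; all
three models recover the planted dependence between a fast post-operative
recovery and later decline, and for the random forest the duration of the
acute post-operative recovery (epoch 4) is the single most important
feature (≈ 0.28 of total importance), followed by the epoch-4 slope.

The same stages are exposed on the command line for users working from CSV
exports (QS Access style, columns `date,steps`):

```bash
perimob simulate --n 75 --seed 1 --out cohort/
perimob preprocess --steps cohort/steps/P0003.csv --surgery-date 2018-03-19 --out norm.csv
perimob segment --steps cohort/steps/P0003.csv --surgery-date 2018-03-19 \
    --age 65 --bmi 29 --out P0003
perimob train --features features.csv --model rf --seed 1 --report report.json
```

## Layout

```
src/perimob/
  epochs.py      epoch labels and window constants
  simulate.py    synthetic cohorts with ground truth
  preprocess.py  CSV ingestion, alignment, normalization, smoothing
  segment.py     six-epoch state machine + 0.25-SD decline rule
  features.py    durations, derivatives, leakage policies, design matrix
  models.py      splitting, three classifiers, metrics, ROC, importances
  pipeline.py    cohort-level orchestration
  cli.py         `perimob` command-line interface
docs/methods.md  modelling assumptions, parameter choices, limitations
```
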