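# spiraldx

Tablet-based assessment of movement disorders from spiral drawings and a
non-motor-symptom questionnaire.

Clinicians routinely ask patients to trace an Archimedean spiral to judge
tremor and bradykinesia. `spiraldx` turns raw stylus recordings of that task —
timestamp, x/y position and pen force at a nominal 240 Hz, two repetitions per
hand — plus the 30-item yes/no Parkinson's Disease Non-Motor Scale (PDNMS)
into a quantitative assessment:

1. **Geometry.** The drawn trajectory is reduced to a signed radial deviation
   from the reference spiral r(θ) = b·θ (max radius 3.75 cm over 4 loops):
   d(t) = r_drawn(t) − b·θ(t), negative when the pen runs inside the template.
2. **Features.** Fourteen model inputs per participant: `QYes` (number of yes
   answers, 0–30) and thirteen motor features `F1c…F13` — the between-arm
   difference of the binned 3–15 Hz distance spectrum (tremor laterality),
   max/mean/std of the distance series, direction-change counts of radius and
   x/y, force mean/std/median, drawing time, and mean/std of the velocity
   series v_i = √((x_i−x_{i−1})² + (y_i−y_{i−1})²)/(t_i−t_{i−1}). Pen-lift
   artefacts are filtered (10 % clipped per end of time-dependent series;
   top 5 % of distance magnitudes removed before the time-independent
   summaries); repetitions are averaged and the stronger affected arm — the
   one with the larger distance-series std — supplies the motor features.
3. **Statistics.** Spearman correlations of features against task labels and
   age, and two-sided Mann–Whitney-U group comparisons with Bonferroni
   correction (c = 14, threshold 0.05/14 ≈ 0.0036).
4. **Classification.** Three diagnostic contrasts — Task 1: Parkinson's
   Disease (PD) vs controls (CG); Task 2: all movement disorders vs CG;
   Task 3: PD vs diverse other movement disorders (DD) — evaluated by
   stratified fivefold cross-validation of a standard-scaler → PCA →
   gradient-boosted-trees pipeline, with ablations (majority dummy,
   questionnaire-only, tablet-only, integrated) and exact Shapley-value
   feature importances.
5. **Simulation.** A synthetic cohort generator (default 27 CG / 24 PD /
   26 DD) with group phenotypes — 4–6 Hz strongly lateralized PD rest tremor,
   5–10 Hz bilateral DD tremor, elevated non-motor yes-probabilities for both
   disease groups — so the whole pipeline runs and is tested without any
   recorded data.

## Worked example

```python
from spiraldx import (CohortConfig, generate_cohort, extract_feature_table,
                      TaskClassifier, ModelConfig)

cohort = generate_cohort(CohortConfig(seed=7))      # 77 synthetic participants
features = extract_feature_table(cohort)            # one row per participant
results = TaskClassifier(features, "Task3", "integrated",
                         ModelConfig(seed=7)).fit()
print(results.summary())
```

```
Task3: ['PD'] vs ['DD']
feature set: integrated (14 predictors, n=50)
stratified 5-fold CV, seed 7

      accuracy  precision  recall    f1  n_test
fold
0        0.800      0.714   1.000 0.833      10
1        0.800      1.000   0.600 0.750      10
2        0.800      0.800   0.800 0.800      10
3        0.800      0.800   0.800 0.800      10
4        1.000      1.000   1.000 1.000      10

mean over folds:
accuracy    0.840
precision   0.863
recall      0.840
f1          0.837
majority baseline accuracy: 0.520
```

The hardest contrast (PD vs. other movement disorders) is classified well
above the 0.52 majority baseline, and the feature attribution shows why —
laterality of the tremor spectrum dominates, with the questionnaire
contributing nothing to this contrast:

```python
print(results.shap_importance().mean_abs_ranking.head(4))
```

```
F1c_DistanceFFT      1.867361
F9_StDevForce        0.891801
F12_MeanVelocity     0.809269
F11_TimeOfDrawing    0.503331
```

`results.error_analysis()` summarizes the misclassified subgroups (count,
mean age, female count, mean QYes, mean Hoehn–Yahr stage), and
`results.plot_importance()` draws the per-fold Shapley distributions.

The same pipeline is scriptable from the shell:

```bash
spiraldx simulate --n-cg 27 --n-pd 24 --n-dd 26 --seed 7 --out cohort/
spiraldx extract  --cohort cohort/manifest.json --out features.csv
spiraldx stats    --features features.csv --out stats/
spiraldx classify --cohort cohort/manifest.json --task 3 \
                  --features integrated --seed 7 --out report.json
spiraldx all      --out run/ --seed 7        # everything, one command
```

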