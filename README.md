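# echoedema

Non-invasive monitoring of cerebral edema from A-mode ultrasonic echo
signals. After an ischemic stroke, brain tissue swells in two phases:
early *cytotoxic* edema (water moves into cells; tissue density and acoustic
impedance rise) followed by *vasogenic* edema (the blood–brain barrier leaks;
density and impedance fall). These acoustic changes leave a signature in the
raw pulse–echo waveform — most visibly a decline in echo amplitude from
about 3 h to 24 h post-onset — which can be quantified with simple
time/frequency-domain statistics and fed to machine-learning models.

`echoedema` implements that analysis end to end for longitudinal rodent-style
cohorts, with a synthetic waveform generator standing in for the in-vivo
acquisitions (no public dataset of intracranial RF echoes exists):

1. **Simulation** — 20 subjects × 9 time points (0, 1, 2, 3, 6, 9, 12, 18,
   24 h) × 4 replicate measurements = 720 echo records from a
   Gabor-pulse scatterer model whose amplitude scale follows a logistic
   severity curve, plus 3 infarct-volume-ratio observations per time point
   (27 total) rising to ≈ 0.482 at 24 h.
2. **Feature extraction** — 13 time-domain statistics
   (maximum, minimum, mean, peak-to-peak, absolute average, variance,
   standard deviation, kurtosis, skewness, RMS, shape factor, impulse
   factor, crest factor) and 9 frequency-domain statistics (mean magnitude,
   centroid frequency, mean-squared frequency, its root, frequency variance,
   mean frequency, total power, average power, peak frequency) per record.
3. **Dataset construction** — z-score outlier replacement by the column
   median, mean imputation, early/late class labels, and per-row regression
   targets from a natural cubic spline through the per-time mean infarct
   ratios:

   `infarct volume ratio = (V_contra − V_unstained_ipsi) / V_contra`

4. **Modeling** — SVM, logistic regression, decision tree and random forest
   classifiers (ACC / AUC / F1) and SVM, random forest, linear and
   feedforward-network regressors (MSE / RMSE / MAE / R²), all under seeded
   10-fold cross-validation with fold-wise standardization.
5. **Statistics** — Kruskal–Wallis across time points with Dunn's post-hoc
   comparisons against 0 h (Holm-adjusted), significance stars, and
   boxplot-ready summaries for the 16 edema-associated features.

## Worked example

```python
import echoedema as ee
from echoedema.pipeline import build_dataset

cfg = ee.PipelineConfig(cohort=ee.CohortConfig(seed=7), seed=7)
records = ee.generate_cohort(cfg.cohort)
observations = ee.generate_infarct_observations(cfg.cohort)
table = ee.extract_feature_table(records)
dataset = build_dataset(cfg, table, observations)

dataset.groupby("time_h")[["maximum", "total_power", "target_ratio"]].median()
```

```
        maximum  total_power  target_ratio
time_h
0.0      1.2344       0.0338        0.0246
3.0      1.1844       0.0323        0.0295
6.0      0.7660       0.0139        0.2299
9.0      0.3405       0.0042        0.4449
24.0     0.3022       0.0038        0.4997
```

The echo maximum and total power are flat through 3 h and then collapse as
vasogenic edema develops, while the spline-interpolated infarct target rises
toward ≈ 0.5 — the phenomenology the classifier and regressor exploit:

```python
clf = ee.crossval_classify(dataset, ee.DEFAULT_SELECTED_16,
                           ee.ClassifierSpec("random_forest", seed=7), k=10, seed=7)
reg = ee.crossval_regress(dataset, ee.DEFAULT_SELECTED_16,
                          ee.RegressorSpec("random_forest", seed=7), k=10, seed=7)
```

```
classification: ACC 0.999 ± 0.004, AUC 1.000 ± 0.000, F1 0.999 ± 0.004
regression:     MSE 0.0005, RMSE 0.0217, MAE 0.0120, R² 0.9889
```

ACC/AUC/F1 score the early-vs-late edema-type classifier (positive class =
late vasogenic); R² measures how much of the infarct-ratio variation the
regressor recovers from the echo features alone.

A note on these numbers: cross-validation here splits at the *record* level,
so replicates of one subject can appear in both training and test folds.
Grouped subject-level splitting (no subject shared between folds) is
available via `group_by_subject=True` and gives a more conservative estimate
of generalization to unseen subjects; record-level splitting is the default
because it matches how such feature tables are commonly evaluated.

The same pipeline is scriptable from a shell:

```bash
echoedema run-all --out runs/demo --seed 7
echoedema simulate --out cohort/ --seed 7        # waveform CSVs + manifest
echoedema train --dataset runs/demo/dataset.csv --task classify \
    --model rf --features single:maximum --out runs/single
echoedema report --dataset runs/demo/dataset.csv --out runs/stats
```

## Layout

```
src/echoedema/
  config.py             cohort + pipeline configuration (YAML round-trip)
  simulate.py           severity curve, echo forward model, infarct ratios
  signal_processing.py  DC removal, one-sided spectra, waveform CSV I/O
  features.py           the 22 features, 16-feature selection, transformer
  dataset.py            cleaning, labels, cubic-spline targets
  modeling.py           CV classification/regression, ROC, FNN
  stats.py              Kruskal-Wallis, Dunn post-hoc, stars, report
  pipeline.py, cli.py   end-to-end runs and the `echoedema` CLI
docs/methods.md         model assumptions, parameter choices, limitations
```
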