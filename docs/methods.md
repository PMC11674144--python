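# Methods

## The problem being modeled

Ischemic cerebral edema progresses from a cytotoxic phase (first hours:
water shifts into cells, tissue density and acoustic impedance rise) to a
vasogenic phase (blood–brain-barrier breakdown: interstitial fluid
accumulates, density and impedance fall). In pulse–echo ultrasound this
manifests as echo amplitudes that are roughly stable for the first ~3 h
after onset and then decline markedly through 24 h. The infarct volume
ratio — the fraction of the ipsilateral hemisphere that fails vital
staining, normalized by the contralateral hemisphere — rises over the same
window toward roughly 0.48, and serves as the severity target for
regression.

The package turns this into a supervised-learning benchmark: classify early
(cytotoxic) vs late (vasogenic) records and regress the infarct ratio from
waveform features, under cross-validation, with the feature trajectories
characterized by rank statistics.

## Synthetic cohort generator

### Severity curve

Severity s(t) ∈ [0, 1] is logistic in hours post-onset:
s(t) = 1 / (1 + exp(−r (t − m))) with midpoint m = 6 h and rate
r = 1 h⁻¹. With these defaults s(0) ≈ 0.0025, s(3) ≈ 0.047, s(6) = 0.5,
s(24) ≈ 1 — flat through the first three hours, saturated by 24 h, monotone
by construction. The functional form is a modeling convenience; only the
flat-then-decline shape matters downstream.

### Echo forward model

Each record is a sum of Gaussian-modulated cosine (Gabor) pulses at the
2.25 MHz transducer center frequency: one strong skull-interface echo early
in the record and 12 weaker parenchyma scatterers at uniform random depths
with relative amplitudes 0.08–0.25 of the interface echo (the bone–tissue
impedance step dominates soft-tissue backscatter by far). Pulse widths span
1.5–3 carrier cycles; phases are uniform. The global amplitude scale is

a = a₀ · (1 − γ · s(t)) · exp(u_subject)

with a₀ = 1, amplitude-decline fraction γ = 0.8 and a per-subject
log-amplitude effect u ~ N(0, 0.1) drawn once and shared by all of that
subject's records (coupling gel, skull thickness, probe placement).
Additive white noise with σ = 0.05 is applied at a fixed scale, and with
probability 0.05 a record receives a slow half-sine baseline excursion of
amplitude 0.3–0.8 (movement/respiration artifact).

Two design points matter for realism of the downstream statistics:

* Because the noise floor is fixed while the echo amplitude declines, the
  record's signal-to-noise ratio falls with severity. This is what moves the
  scale-invariant shape features — kurtosis, skewness, shape/impulse/crest
  factors fall toward their Gaussian-noise values, and the power-weighted
  mean frequency rises from the 2.25 MHz carrier toward the broadband noise
  mean — so the late records differ from early ones in shape, not just in
  scale. The initial scatterer amplitudes (0.15–0.5) left the clean signal's
  crest factor too close to the white-noise crest for a reliable 0 h-vs-24 h
  contrast; the 0.08–0.25 range fixes this and is the more physical choice.
* Each pulse carries a small positive envelope component (30 % of the Gabor
  envelope added to the oscillation). This gives high-SNR records a positive
  amplitude skewness that decays with severity, mimicking the asymmetric
  compression/rarefaction response of real pulse echoes.

Sampling: 50 MSa/s for 40 µs (2000 samples/record). The acquisition
hardware this emulates ran at 500 MSa/s; the tenfold reduction keeps arrays
small while oversampling the carrier >20×, and the hardware rate remains a
config value. Records are emitted as already-averaged acquisitions (the
oscilloscope's 64-fold averaging is treated as internal to acquisition, not
a pipeline step).

### Infarct observations

Three observations per time point: ratio = 0.482 · s(t) + ε with
ε ~ N(0, 0.03), clamped to [0, 1]. 0.482 is the asymptotic 24 h infarct
ratio; 0.03 is a plausible between-animal staining/volumetry spread giving a
standard error of ~0.017 on the per-time mean of three animals. The direct
`infarct_ratio` computation from hemisphere volumes warns on (and keeps)
negative values rather than clamping; clamping is applied only when
generating synthetic observations.

### What the generator does not emulate

No wave propagation, attenuation/dispersion, speckle statistics from
sub-resolution scatterers, skull reverberation, or probe-angle variation;
class structure is driven by a single latent severity. Passing tests
therefore show that the pipeline correctly extracts and exploits an
amplitude/shape signature of the programmed form — not that real
intracranial echoes are this separable. Real-data accuracy claims require
real data.

## Feature definitions

The 22 features follow the classical machinery-diagnostics set, with two
conventions kept deliberately:

* Kurtosis F8 and skewness F9 use 1/N central-moment numerators over a
  standard deviation computed with 1/(N−1) — Pearson (non-excess) kurtosis
  with a mildly biased normalizer, implemented literally rather than
  "corrected" (negligible at N = 2000).
* Impulse factor F12 = peak-to-peak / mean |x| and crest factor
  F13 = peak-to-peak / RMS are built on peak-to-peak, not maximum.

The root-mean-square frequency (F17) is taken as √F16 so that it is in Hz
and distinct from the mean-squared frequency; it is outside the 16-feature
modeling set, so the choice cannot affect headline metrics. Time-domain
features are computed after DC removal (so the mean feature is ~0 by
construction); spectra use a one-sided scaling under which an on-bin tone
of amplitude A has magnitude A and power A²/2, and summed power equals the
mean-square amplitude (Parseval). N is the sample count for time-domain
features and the one-sided bin count for the spectral averages. Peak
frequency breaks ties toward the lowest frequency. Degenerate records
(zero RMS/SD after DC removal) are flagged and their ratio features
reported missing, never infinite.

## Dataset construction

Cleaning is the single-pass z-score rule: per column, entries with
|z| > 3 (z from the column mean and SD) are replaced by the pre-replacement
column median, then remaining missing values are mean-filled. The rule is
idempotent only when the cleaned columns keep their tails inside the
threshold; on heavy-tailed columns (artifact-bearing records) a second pass
can flag new outliers because replacement shrinks the SD. The pipeline
applies exactly one pass.

Class labels: time ≤ 4.5 h → early cytotoxic (320 rows at defaults), else
late vasogenic (400 rows). The boundary sits between 3 h (histology shows
early edema) and 6–9 h (vasogenic changes) and must split the observed time
range into two non-empty classes.

Regression targets: a natural cubic spline (zero second derivative at the
ends) through the per-time mean infarct ratios, evaluated at each row's
acquisition time and clamped to [0, 1]. With all rows at knot times the
spline reduces to per-time means; it exists to define targets at arbitrary
intermediate times.

## Modeling

10-fold cross-validation, stratified for classification, plain seeded
shuffle for regression. Standardization is fit on training folds only by
default; whole-table pre-normalization is available as a config switch for
parity with workflows that normalize before splitting, at the cost of mild
leakage. Regression hyperparameters: linear-kernel SVR with C = 1; random
forest with 100 trees, depth ≤ 20, min split 5, min leaf 1; OLS; MLP with
hidden layers (64, 32), ReLU, adam, learning rate 10⁻³, 50 epochs, batch 64
(implemented with scikit-learn's MLPRegressor; early stopping disabled so
the full epoch budget always runs; a zero-epoch fit is not supported).
Classifier hyperparameters are scikit-learn defaults (logistic regression
with max_iter = 1000), recorded in each run's config snapshot. AUC and F1
take late-vasogenic as the positive class; ROC curves use grouped ties and
trapezoidal area.

Record-level splitting is the default; `group_by_subject=True` switches to
grouped folds in which no subject appears in both training and test. The
record-level numbers are optimistic about generalization to new subjects —
replicate waveforms of one animal are highly correlated — and the grouped
option exists precisely to quantify that gap.

## Trajectory statistics

Per feature: Kruskal–Wallis across the nine time groups (tie-corrected H,
chi-square approximation with 8 degrees of freedom; degenerate all-equal
input returns H = 0, p = 1) and Dunn's post-hoc z-tests on mean ranks with
the same tie correction. All 36 pairs are computed and Holm-adjusted
(configurable to Bonferroni or none); the report presents the eight
comparisons against the 0 h baseline, the comparison the boxplot annotation
convention highlights. Stars: *** p < 0.001, ** p < 0.01, * p < 0.05,
strict inequalities.

## Problem sizes and numerical choices

Default problem sizes — 720 records of 2000 samples, 27 staining
observations, 10 folds — run the full pipeline in well under a minute on
one core; statistical validity checks use 1000-replicate null simulations.
Determinism: the cohort is a pure function of the config (subject effects,
scatterer geometry, noise and artifacts all derive from the config seed; the
staining observations use a separate child stream so the two are
independently reproducible), and every estimator receives an explicit seed,
so a rerun with the same config is byte-identical down to the CSV artifacts.
Waveform CSVs store amplitudes via `repr` (shortest round-tripping decimal),
making read∘write exact.

## Known limitations

* The generator's single latent severity makes classes more separable than
  real intracranial data; reported accuracies characterize the pipeline, not
  the clinical problem.
* The early/late class boundary is a labeling rule over time, not a
  histological measurement per record.
* Pairing 720 records with 27 staining observations via a time-only spline
  assigns every record at a time point the same target, ignoring
  between-subject severity differences.
* Chi-square and normal approximations in Kruskal–Wallis/Dunn assume group
  sizes of the default magnitude (80 per time point); very small cohorts
  should use exact or permutation tests, which are out of scope.
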