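# Methods

## Scope and model

`eegage` implements an end-to-end analysis of age-related structure in
frontal EEG recorded under general anaesthesia: stable-segment selection,
spatio-spectral feature extraction, nested stacked-ridge age prediction with
Monte Carlo cross-validated model comparison, and two clinical statistical
models (a log-power mixed model and a burst-suppression logit model). A
synthetic cohort generator with explicit ground truth provides the data;
all empirical statements in this note are computed by the test suite or by
`scripts/acceptance.py`.

## Synthetic cohort generator

### Spectral model

For a patient with chronological age `a`, latent brain-age offset `δ`
(Gaussian, SD 8 yr; the *effective* spectral age is `a + δ`), drug `d`, and
per-patient broadband gain `g` (Gaussian, SD 3.5 dB), the noiseless log PSD
in dB re 1 µV²/Hz is

```
dB(f) = b0 − 10·χ·log10(max(f, 0.5))                      aperiodic background
      + A(a+δ)·exp(−(f − p(a+δ))² / (2w²))                 frontal alpha bump
      + s_d·(a+δ) + g                                       age slope and gain
      + [d = sevo]·(3.6 − 1.00·(ln f − ln 12.32))           drug offset + tilt
```

with defaults `b0 = 16 dB`, `χ = 1.8`, alpha peak `p` declining from
11.5 Hz at age 18 by 0.03 Hz/yr (clipped to 8.3–12.7 Hz), alpha amplitude
`A` declining from 10 dB by 0.05 dB/yr, width `w = 1 Hz`, and age slope
`s_d = −0.10 dB/yr` under both drugs. The aperiodic term is flat below
0.5 Hz so total power is finite; all fidelity checks run at ≥ 1 Hz.

Parameter rationale:

* **χ = 1.8 and A = 10 dB** place the analytic SEF95 at 9.2–12.0 Hz across
  ages 18–90 for *both* drugs. This matters because anaesthesia in the
  emulated setting is titrated to keep SEF95 in 8–13 Hz regardless of drug;
  with a steeper background the sevoflurane arm's low-frequency tilt pushes
  SEF95 below 8 Hz and the entire arm would fail the stability screen,
  which no real titrated cohort does.
* **Gain SD 3.5 dB** encodes electrode/skull/impedance variability. It is
  chosen to match the uncertainty structure of published frontal-EEG ageing
  analyses, whose age-slope confidence intervals imply a patient-level
  power SD of roughly 4 dB and whose power-level-only age models perform
  only a few years better than chance. It is also what makes the nested
  model comparison informative: flat gain corrupts power *levels* (total
  and alpha power) but not spectral *shape* or cross-channel correlation,
  so the richer feature sets genuinely add information. The alpha
  amplitude slope (−0.05 dB/yr, i.e. 3.6 dB over the adult range) is scaled
  against that gain SD so the alpha-power feature carries age information
  beyond the broadband level, as each nested feature set must.
* **Reference frequency 12.32 Hz** is the mean log-frequency of the 1–30 Hz
  analysis grid, so the drug main effect of a centred-log-frequency
  regression equals the generator's offset (+3.6 dB) by construction.

The drug × log-frequency interaction is −1.00 dB per unit natural-log
frequency. (Printed descriptions of such interactions sometimes say "per
hertz"; the model here, like the regression it feeds, is linear in log
frequency.) A `sevo_age_coded=False` switch freezes every age input of the
sevoflurane spectrum (slope, alpha peak and amplitude, spatial mixing) at
age 54 — the *drug-specific age coding* condition used by the
generalization experiment, reflecting the finding that age-related EEG
signatures can be anaesthetic-specific. The default truth keeps sevoflurane
fully age-coded.

### Signal synthesis and spatial structure

The spectrum is split into an aperiodic component and the (non-negative)
excess alpha power, which add exactly to the target PSD. Each component is
realised as Fourier-domain shaped Gaussian noise; channel `c` mixes a shared
source `u` with an independent source `v_c`,
`x_c = λ_c·u + sqrt(1 − λ_c²)·v_c`, separately per component. Each channel
therefore carries the target PSD exactly (in expectation) while the
cross-channel correlations `λ_c λ_c'` encode age: the 4×2 loading matrix
`λ(age)` interpolates linearly between a "young" and an "old" profile,
separately for the broadband and alpha sources. A −30 dB white noise floor
keeps every band covariance full rank.

Empirically (seeded tests): a 600-s artifact-free record deviates from its
patient-specific target spectrum by < 1 dB at every 0.25 Hz grid frequency
in 1–30 Hz.

### Burst suppression and artifacts

Each patient's burst-suppression proportion follows
`logit(p) = −2.5 + 0.30·z(age) + 0.85·z(brain age) + 0.50·ASA3
− 0.99·z(brain age)·ASA3 + ε`, `ε ~ N(0, 0.5)`. The z-scales default to the
cohort's population moments (age SD 20.78 yr for uniform 18–90; brain-age
SD ≈ 22.38 yr including the latent offset) so that a sample-z-scored
refit recovers the coefficients; the logit noise makes the proportions
overdispersed, which keeps quasi-binomial standard errors honest.
Suppression is realised as 2–10 s episodes attenuated below 2 µV
peak-to-peak (50 ms cosine ramps), alternating with 1–4 s bursts inside one
contiguous region at a random position — clinically, burst suppression
clusters in periods of excessive depth, and clustering is what leaves the
rest of the record usable. Artifacts are biphasic transients (> 300 µV
peak-to-peak, 0.2–1 s) at 0.2/min.

What the generator does **not** emulate: physiological source geometry (no
head model), non-stationary drug titration within a recording, opioid or
haemodynamic confounders, and realistic artifact morphology diversity.
Passing tests therefore demonstrate correctness of the *analysis machinery*
and identifiability of the encoded effects, not clinical performance on
real EEG.

## Preprocessing

60-s windows, 10-s shift (`n = floor((T − 60)/10) + 1`). A window is
retained iff every channel's peak-to-peak lies strictly in (0.1, 250) µV —
the lower bound removes disconnection/isoelectric signal, the upper bound
(a package choice; high-voltage artifacts are far above frontal anaesthesia
EEG) removes artifacts — and iff at most 2% of its samples overlap detected
burst suppression. The explicit suppression screen exists because a 60-s
window containing a short 2 µV episode passes the amplitude bounds, yet
suppressed EEG must never enter model construction; without it the
age-dependence of suppression leaks into the spectral features and biases
the mixed model's age slope (measured: −0.123 vs truth −0.100 dB/yr).

SEF95 uses the same Welch settings as the features module (4-s Hann
windows, 50% overlap, 0.25 Hz grid) over 0.5–30 Hz: the smallest grid
frequency at which cumulative power reaches 95% of the in-range total. The
0.5 Hz lower bound excludes DC drift. The stable segment is the longest run
of consecutive retained windows whose 4-channel-mean SEF95 lies in
8–13 Hz; equal-length runs resolve to the earliest (deterministic), and a
rejected window breaks a run. Patients without a qualifying window are
excluded with a machine-readable reason in the QC table.

The burst-suppression detector — a stand-in for site-specific annotation
procedures, which are not public — flags samples where the 0.2-s rolling
peak amplitude stays below the detection threshold on all channels for
≥ 0.5 s; the burst-suppression ratio is the flagged fraction of the
recording. The threshold adapts to the patient's signal level
(0.2 × median envelope, floored at 1 µV and capped at an absolute 5 µV):
a purely absolute threshold misclassifies continuously active low-amplitude
EEG (low-gain patients) as suppressed, which would both corrupt the
suppression outcome and selectively exclude low-power patients from the
stable segment — a selection correlated with latent brain age.

## Features

Welch PSDs are averaged over the stable segment's windows. Band-pass
filtering for the covariances uses zero-phase symmetric FIR kernels
(transition width 25% of the lower band edge, floored at 0.15 Hz), applied
to the continuous record so the window slices are free of filter edge
effects. Per-window covariances are averaged and regularised with OAS
shrinkage toward a scaled identity (closed form; guarantees positive
definiteness for degenerate inputs). The covariance block is vectorized by
whitening at a reference matrix, matrix logarithm, and √2-weighted upper
triangle (10 values per band, 50 total). At model-fit time the reference is
the affine-invariant geometric mean of the *training* covariances per band
(fixed-point iteration, tolerance 1e-8); identity when used standalone.

The scalar alpha-power feature averages 8–13 Hz (the monitoring-band
definition) while the covariance alpha band is 8–15 Hz — both definitions
are used where their respective analyses use them. The 16 spectrum features
sample the log channel-mean PSD at the grid bins nearest to 16 evenly
spaced frequencies in [1, 30] Hz. Power features are natural-log
transformed; dB is used only for reporting. Known numerical caveat: the low
band's 0.1 Hz edge lies below the 0.25 Hz PSD grid, so its
covariance-diagonal vs PSD-integral consistency is only loose (~40%),
against ≤ 15% for the other four bands.

## Age-prediction models

Nesting order: total power ⊂ + alpha power ⊂ + power spectrum ⊂ + spatial
patterns, plus a mean-predicting dummy. Each feature set gets a level-1
pipeline (tangent re-mapping for the spatial block → z-scoring → ridge with
penalty chosen on a log grid 1e−3…1e5 by efficient leave-one-out GCV), all
fitted inside the training fold; a shuffled 10-fold produces out-of-fold
level-1 predictions that train the level-2 ridge. Stacking gives each set
exactly one input at level 2, so model comparisons are balanced in
dimensionality and adding a set can only help through information (a
pure-noise extra set shifts the median MAE by < 1 yr; a single-set stack
performs within 0.5 yr of the plain ridge on that set).

Scoring uses Monte Carlo CV: 100 shuffle splits at 10% test size (the test
fraction is a package choice keeping training folds large at n ≈ 170), the
identical split sequence for every model, per-split MAE and test-fold
R² = 1 − SS_res/SS_tot. Comparisons report per-split paired ΔMAE,
percentiles by linear interpolation (so P25 of 1..100 is 25.75), and strict
superiority counts. Cross-validated brain-age tables give reference
patients out-of-fold predictions (10-fold) and held-out populations
predictions from a refit on all reference patients. The drug-generalization
grid fits per split three models (propofol-train, sevoflurane-train,
pooled) and scores seven cells; a drug group smaller than the internal fold
count yields NaN cells rather than an error. All seeds fan out
deterministically from one base seed.

## Clinical statistical models

**Log-power mixed model.** Channel-mean PSD → dB → long table (patient ×
0.25 Hz bin over 1–30 Hz; 117 bins). REML fit with patient random
intercepts; age and log frequency are centred at their sample means so main
effects are interpretable at a reference patient/frequency; Wald 95% CIs.
A singular random-intercept fit falls back to OLS with a loud warning. With
the random-intercept variance at zero the fixed effects coincide with OLS
(tested to 1e-4).

**Burst-suppression model.** Quasi-binomial GLM (logit link) on the
per-patient suppressed proportion: scaled age, scaled brain age, binarised
ASA (1–2 vs 3), and the two ASA interactions; scale estimated by Pearson
X², t statistics on the residual df, optional duration weights. `exp(β)` is
reported as an odds ratio per predictor SD. An empirical-logit OLS
(ε = 0.5/n) is available behind a flag, since the printed inference in this
literature does not always disambiguate the estimator. Because age is in
the model, the brain-age coefficient captures the age-prediction error.
Recovery tests use the generator's latent brain age, isolating the
estimator from machine-learning attenuation; the end-to-end path with
predicted brain age runs in the pipeline.

## Problem sizes and seeds

The test suite runs seeded, scaled-down studies: 170-patient reference
cohorts with 600-s recordings, 25 CV splits, 20 recovery replicates with
360-s recordings, and a 250-patient two-drug cohort with 480-s recordings
for the generalization direction. `scripts/acceptance.py` uses 100 CV
splits and the same cohort sizes, deriving every seed from `--seed`.
Recovery coverage criteria are ≥ 17/20 replicates (95% CIs for the mixed
models, ±2 SE for the logit coefficients).

## Known limitations

* The burst-suppression detector is amplitude-based; it would miss
  suppression defined by other morphologies and over-count low-amplitude
  artifacts.
* The generator's between-drug difference under the default truth is purely
  spectral (offset + tilt); spatial mixing differs by drug only in the
  drug-specific-coding variant.
* Mixed-model CIs assume independent residuals across frequency bins within
  patient beyond the random intercept; the alpha-bump misfit violates this
  mildly.
* Brain-age deltas are not bias-corrected for regression toward the mean
  (none is applied in the modelled analyses either); the brain-age
  coefficient in the logit model is interpreted conditionally on age
  instead.
* EDF output is 16-bit; round-trip error is bounded by the per-channel
  quantization step (tested).
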