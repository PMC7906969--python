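# Methods

## Scope and model

`eegqual` scores how much of a recording segment represents the
physiological source of interest rather than noise. Two models are
provided, reflecting whether the noise source can be recorded in the same
modality as the signal.

### Unimodal model

The unimodal model is fitted to three labelled feature-table collections:
clean data (C), raw data with artifact present (R), and the noise source
(N). Its assumptions are:

* each of the 30 quantitative features carries class information
  marginally; no joint density across features is modelled;
* the clean and noise distributions of a useful feature are close to
  unimodal and separable, with raw straddling the two;
* the stored fitting values are representative enough that empirical
  proportions over them estimate the class CDFs.

Per feature, Gaussian KDEs with Scott's-rule bandwidth (n^(−1/5)·σ̂ in one
dimension) are fitted to each class. The critical value v* is the
equal-prior Bayes threshold between the clean and noise densities. Three
error probabilities are computed by comparing the clean and noise KDEs at
each class's stored values, and their deviation from the ideal profile
(0 for C and N, 0.5 for R) gives E_total ∈ [0, 2.5], the feature-inclusion
statistic. Scoring uses empirical proportions, not KDE integrals: the KDEs
enter only through the critical-value search and the error probabilities.
This keeps the sub-score exactly reproducible from the stored values and
makes model serialisation/reload bit-identical.

The sub-score's lower branch is implemented literally as defined: values
far below v* (deep in the noise tail) score near 0.5 while values just
below v* score near 0. The branch is therefore non-monotonic pointwise, but
the class *means* still land on the 0.25/0.75 design targets, which is what
the score is calibrated on. The branch inequalities are strict for the
clean proportion and non-strict for the noise proportion; under the
reversed orientation (noise above clean) they are mirrored exactly, which
makes global negation of all feature values an exact symmetry of the model
(verified by test).

### Multimodal model

When noise is only measurable through another modality, quality is scored
through a clean-vs-raw segment classifier. Q_M = 1/2 + (P_C − P_R)/2 is the
single closed form of the two-branch definition; the two probabilities are
deliberately treated as free numbers in [0, 1] rather than a normalised
pair, so probability tables from classifiers whose per-segment outputs do
not sum to one (e.g. crop-averaged deep networks) can be scored unchanged.
The bundled reference classifier is multinomial logistic regression over
per-channel relative band powers plus log total power, standardised, with
balanced classes obtained by seeded down-sampling of the larger class. It
exists to exercise the pathway end to end at desk scale; it makes no claim
to match the behaviour of a deep network on real recordings, and any model
honouring the (P_C, P_R) contract can be plugged in.

## Feature definitions and numerical choices

* Spectral features use the plain one-sided periodogram (rectangular
  window, no detrending). Band edges: δ 1–4, θ 4–8, α 8–12, μ 12–16,
  β 16–25, γ 25–40 Hz; band integration is over half-open intervals
  [lo, hi). Relative power divides by total power over the full spectrum,
  so the six relative powers sum to less than 1 (0–1 Hz and >40 Hz are
  uncovered).
* The single spectral-entropy feature is the Shannon entropy (natural log)
  of the periodogram normalised to a probability distribution. Signal
  entropy z-normalises the samples, histograms them into 100 bins over the
  observed range, and takes Shannon entropy of the bin proportions; a
  constant signal returns 0.
* Lempel–Ziv complexity binarises at the arithmetic mean (≥ mean → 1),
  counts LZ76 phrases c(n) with the Kaspar–Schuster scan, and normalises as
  c(n)·log₂(n)/n. The test suite checks the phrase count exhaustively
  against a definition-based parser for all binary strings up to length 12.
* Variance/SD use the n−1 denominator; skewness is the bias-corrected
  sample coefficient; kurtosis is excess (Fisher). Energy-family features
  (curve length, energy, Teager energy, sixth power, sum) are totals over
  the epoch, not means — epoch length is fixed within a study so the
  distinction does not affect class separation.
* The critical-value search evaluates the empirical equal-prior error on a
  2001-point grid over the pooled hull of the clean and noise values, with
  the midpoint of the class means appended as a candidate; ties are broken
  toward that midpoint, so fully degenerate overlap returns it exactly.
* Features with fewer than two distinct values in the clean or noise class
  have no defined KDE; they are marked unusable, excluded from scoring at
  any threshold, and reported with a warning. Constant epochs are skipped
  during feature-table construction.
* Model files are JSON; floats are serialised at round-trip precision, so a
  reloaded model scores bit-identically.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `inclusion_threshold` | 0.35 | – | E_total cutoff for the scored feature set; the sweep supports choosing it |
| `min_samples` | 10 | epochs/class/feature | fitting floor below which fit refuses |
| epoch length (unimodal) | 60 | s | feature stability; matches the study layout |
| epoch length (multimodal) | 30 | s | segment classifier input length |
| sweep grid | 0–2.5 step 0.05 | – | threshold sweep resolution |
| `k`, `holdout_fraction` | 10, 0.10 | – | repeated random-subsampling validation |

Cross-validation is, by design, ten independent random 90/10 subsamplings
(not partitioned folds); a `partitioned=True` flag provides classic k-fold
as an alternative. Reported spread is the mean across folds of within-fold
SDs.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *shape* of the mobile-EEG study the methods
target: 100 Hz sampling, 58-channel (unimodal) and 20-channel (multimodal)
montages, 6-minute sessions, 4 EOG channels, 1-minute unimodal epochs and
30-second multimodal segments — including the bookkeeping (8 subjects ×
58 channels × 6 epochs = 2,784 channel-epochs; 568 clean and 808 raw
motion segments). Clean EEG is 1/f-coloured Gaussian noise (exponent 1.0,
background 10 µV rms) plus a 10 Hz alpha component (5 µV); ocular noise is
raised-cosine blinks (rate 0.25/s, width 0.4 s, amplitude 150 µV,
alternating polarity across the four EOG channels) over a slow drift
(3 µV rms); raw data adds the noise through a random front-weighted gain
matrix (volume-conduction stand-in, gain 0.5); motion artifacts are three
gait harmonics whose fundamental rises with treadmill speed
(0.5 + 0.375·mph Hz, 2 Hz for free walking, 30 µV base amplitude). The
amplitude and rate defaults were chosen once as plausible mid-range values
producing separable-but-not-trivial class structure.

What the surrogates do **not** have: non-stationary artifact statistics,
saccades/muscle/cardiac noise, channel-specific impedance drift, real
volume-conduction geometry, or the heavy-tailed amplitude distributions of
real EEG. Consequently, passing pipeline tests demonstrates that the
machinery is correct and calibrated under its own assumptions — not that
the specific feature rankings found on real recordings will be reproduced.
One visible consequence: on desk-scale synthetic studies most raw epochs
fall on the clean side of the density comparison, so P(error|R) ≈ 0 and
E_total floors near 0.5 even for perfectly separating features. Tests and
examples on these scaled studies therefore fit with an inclusion threshold
of 0.5; the ordering and harness properties they verify are
threshold-agnostic.

## Problem sizes

The test suite runs scaled studies (2–3 subjects, 6–12 channels, 1–2 minute
sessions) chosen so the whole suite completes in well under a minute per
module while retaining statistical power for the properties asserted; the
design-target simulation uses 2,000 samples per class with 2,000 held-out
draws per class, where the empirical-CDF means are stable to ±0.005. The
count-arithmetic checks generate the full-size study layouts.

## Known limitations

* The unimodal sub-score is non-monotonic below the critical value (by
  definition, kept deliberately); individual epoch scores deep in the noise
  regime should be interpreted through the class-mean calibration, not
  pointwise.
* E_total's raw-class term assumes the raw collection is an even
  signal/noise mixture; persistent low-grade contamination (raw ≈ clean)
  pushes P(error|R) toward 0 and penalises even well-separating features.
* The reference multimodal classifier is linear over band-power summaries;
  artifacts that only alter higher-order temporal structure require a
  stronger plug-in classifier.
* Scoring a feature vector outside the fitted value hulls relies on the
  empirical-proportion tails (0 or 1); no density extrapolation is
  attempted.
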