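# Methods

## Problem and pipeline

The package assesses pain level from prefrontal fNIRS: two haemoglobin
measures (ΔHBO₂, ΔHHB, µmol/L) on 24 channels at 50 Hz, recorded under a
block protocol (60 s baseline; four stimulation conditions — low/high
electrical stimulation of arm/hand, abbreviated LA/HA/LH/HH — six 10 s
stimuli per condition, each followed by 40 s rest, condition order
counterbalanced per subject). The analysis reduces each subject to 36
labelled 10 s epochs of one averaged time series per measure, extracts
ten statistical features per epoch and measure, fuses them, and
classifies Baseline / Low Pain / High Pain with leave-one-subject-out
cross-validation.

## Synthetic cohort generator

The generator emulates the statistical structure the downstream analysis
assumes, with ground truth for every stage. Per channel it sums:

- **Condition responses**: a double-gamma haemodynamic impulse response
  (6 s peak delay, 16 s undershoot delay, undershoot ratio 1/6, unit
  dispersion, 32 s support) convolved with each condition's stimulus
  boxcar, peak-normalised so the configured amplitude is the peak
  response in µmol/L. Defaults: ΔHBO₂ 0.3 (LA), 0.4 (LH), 0.8 (HH),
  1.0 (HA); ΔHHB = −0.3× the ΔHBO₂ value (inverted and smaller, with
  high-pain magnitudes strictly above low-pain ones). The exact HRF
  shape is irrelevant downstream; only the amplitude ordering matters.
- **Systemic physiology**, shared across channels and scaled by a
  per-channel gain (1 ± 0.2): cardiac 0.2 µmol/L at 1 Hz, respiratory
  0.15 µmol/L at 0.25 Hz, random phases.
- **Slow components per channel**: a linear drift with slope magnitude
  0.15–0.45 µmol/L/min (random sign) and a slow vascular oscillation
  (0.004 Hz, amplitude 0.5–1.5 µmol/L, random phase). The drift
  magnitude is floored away from zero so every clean channel's raw range
  is dominated by slow physiology — the regime in which the
  relative-range statistic is meaningful at 50 Hz.
- **Sensor noise**: white, sd 0.01 µmol/L.

With these values a clean channel's relative range stays below ~0.04
while artifact channels exceed ~0.6, mirroring real recordings where
retained channels sit well under the 0.1 threshold.

Contamination: a configurable fraction (default 3/24) of channels
receives spikes (5/min, ±10× the clean range, single-sample) and two
square pulses (2 s, same amplitude); spike times are drawn once per
subject and injected into both measures, since a bad optode corrupts
both. Two channels (indices 18 and 22) are dead by default and rendered
exactly flat. Determinism: each subject's RNG is seeded by
`(rng_seed, crc32(subject_id))`, so cohorts are bit-reproducible and
subjects independent; counterbalancing uses a separate seed stream and a
per-subject random permutation of the four conditions (a stronger
randomisation than any fixed alternation scheme, and configurable).

What the generator does **not** emulate: optical-density/Beer–Lambert
forward modelling, channel-specific haemodynamic topography (all clean
channels share the response up to gain), serially correlated (1/f)
sensor noise, motion artifacts that are *not* large relative to the
signal, and inter-subject variability in HRF shape or response latency.
Consequently, passing tests demonstrate the pipeline's mechanics —
counts, recovery of injected structure, invariances, chance-level
behaviour — not expected classification accuracy on real cohorts, where
class overlap is far larger.

## Channel QC

`RR = range(diff(x)) / range(x)` on the **raw, unfiltered** channels,
using the unscaled first difference (no division by Δt: the 0.1
threshold is calibrated for sample-to-sample differences at 50 Hz, and
Δt-scaling would shift it). Channels with `RR > 0.1` (strict) are
rejected; flat channels (range ≤ 1e−12 µmol/L, covering dead
electrodes) are rejected as a separate category because the ratio is
undefined there. The retained set is computed once per subject on
ΔHBO₂ (configurable) and applied to both measures — optode integrity is
per channel, not per measure. Subjects losing strictly more than 70% of
channels are excluded. `removed_fraction` is computed as
`(n_input − n_retained)/n_input` so the exact-70% boundary is
float-exact.

## Preprocessing

4th-order Butterworth low-pass, cutoff 0.16 Hz, applied zero-phase
(forward–backward, reflective padding) by default: the features are
amplitude/shape statistics and phase distortion would bias them; a
causal mode exists for comparison. At 50 Hz this leaves the cardiac
band attenuated by ≫60 dB and the passband (≤0.05 Hz) flat to within
0.01%.

CAR subtracts the cross-channel mean at each sample. Note the algebraic
degeneracy: CAR followed by averaging the *same* channels is identically
zero. The default pipeline therefore computes the averaged single
series from the filtered (non-CAR) channels and applies CAR only in the
per-channel topography path, where it is meaningful; a
`strict_paper_order` flag reproduces the literal filter→CAR→average
composition (zero output) for documentation and tests.

Epoching: one 10 s epoch per stimulus event starting exactly at onset
(no haemodynamic-lag offset by default; the epoch then captures the
response's rising edge), baseline split into consecutive 10 s windows,
and six rest windows added per subject to balance the classes. The rest
windows are drawn from the six **earliest** rest intervals, taking the
**last** 10 s of each — the window immediately prior to the next
stimulation, where the previous response's tail (undershoot at ~16 s,
negligible past ~30 s) has decayed. Taking the first 10 s instead would
label peak post-stimulus haemodynamics as baseline.

## Features

See the table in the README. Conventions: `h_peak = max |h|` (the
standard crest/impulse/margin-factor convention); variance is the
population variance (divide by the count); statistics of the first
difference h′ are normalised by its own length n−1 (a sum written over
n elements of a length-(n−1) sequence is unsatisfiable); log energy
uses the natural log with h² floored at 1e−300 (floor events are
counted and logged). Degenerate epochs are flagged, not poisoned:
constant epochs make mobility/complexity undefined, zero-absolute-mean
epochs make the amplitude ratios undefined; such rows are dropped from
the feature table with a logged count. Scale/offset behaviour (tested):
crest/shape/impulse factors and mobility/complexity are scale-invariant;
range and the MAD of h′ scale linearly, the variance of h′
quadratically, the margin factor as 1/a; the derivative/range features
are offset-invariant while the amplitude ratios are not.

## MRMR

Greedy forward selection under the difference (MID) scheme — the
canonical deterministic variant: first pick maximises relevance (plug-in
mutual information with the class, nats); each next pick maximises
relevance minus mean MI with the already-selected set. Continuous
features are quantile-discretised (10 bins; duplicated quantile edges
collapse). Ties break by input column order. Inside LOSOCV the ranking
is recomputed per training fold by default (no test leakage); a global
mode ranks once on the full table for comparison with analyses that
report a single feature list. Note that plug-in MI on binned data has a
positive bias of order (bins−1)²/2n, so MID scores of weakly informative
features can go negative; a constant feature (score exactly 0) is
therefore not guaranteed to rank last in general.

## Classification

Hyperparameters are fixed per family and measure mode (the values an
offline Bayesian search produced; re-tuning is deliberately out of
scope as it is wall-clock dependent and would leak test subjects if done
on the full dataset). SVM and k-NN are scikit-learn; "kernel scale" s
maps to an RBF gamma of 1/s², the polynomial kernel uses degree 3 with
coef0 = 1, and one-vs-all coding wraps the SVC in a one-vs-rest
meta-estimator. The discriminant family is a small purpose-built
estimator: pooled within-class covariance, `gamma` blending toward the
diagonal, `diag_linear` keeping only the diagonal, `pseudo_linear`
inverting by pseudo-inverse, and `delta` zeroing small linear
coefficients; numeric parity with any particular toolbox is not claimed.
k-NN's 211-neighbour preset is clamped to the training-fold size with a
warning when folds are smaller than that.

LOSOCV holds each subject out exactly once; standardisation and
(per-fold mode) MRMR are fitted on training subjects only, which is
directly testable through `fit_fold`. Metrics from each fold's 3×3
confusion matrix: accuracy = trace/total; per-class one-vs-rest
sensitivity, specificity and F1, macro-averaged (unweighted mean;
classes absent from a fold are excluded from the mean rather than
counted as zero); aggregates are mean ± sample std (ddof = 1) across
folds, reported in percent.

## Statistics

Per feature: one-sample KS against a normal with estimated mean/sd
(asymptotic p, no Lilliefors correction), one-way ANOVA with the
classical between/within decomposition and df = (k−1, N−k), and
Bonferroni post hoc tests using the pooled ANOVA MSE
(`se = sqrt(MSE(1/n_a + 1/n_b))`, t on the within df,
`p_adj = min(1, 3·p_raw)` for three classes). Both Bonferroni-adjusted
and unadjusted confidence bounds are emitted, since published post hoc
tables often print unadjusted bounds next to adjusted p-values. A
Levene-type homogeneity check (ANOVA on absolute deviations from group
means) is reported but never gates the analysis.

## Problem sizes and numerical choices

The bundled study-scale cohort is 27 subjects × 2 measures × 24
channels × 63,000 samples, processed subject-by-subject so peak memory
stays near one subject (~25 MB). Unit tests use a reduced protocol (2
repetitions, 20 s rests) that preserves every structural property at a
fraction of the cost; the acceptance script and acceptance tests use the
full 27-subject protocol for the dataset-organisation counts,
classification and chance-level checks, and 20 independently seeded
reduced cohorts for QC recovery. Epoch alignment uses
`round(onset × fs)`; events whose windows exceed the recording are
skipped with warnings (segmentation) or recorded as per-event errors
rather than crashing. Filter padding is scipy's default reflective
(odd) extension.

## Known limitations

- Synthetic separability is far above realistic cohorts; accuracy
  numbers on synthetic data characterise the pipeline, not the method's
  clinical performance.
- No artifact *correction* (spline/wavelet motion repair) — channels are
  rejected outright, as in the modelled workflow.
- No region-of-interest analysis: all retained channels are averaged
  into one series, which suppresses spatial information (the topography
  path retains per-channel summaries only).
- Frequency-domain and cepstral features are out of scope.
- The discriminant estimator's gamma/delta semantics approximate the
  MATLAB conventions; exact numerical parity is not claimed.
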