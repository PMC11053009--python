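# Methods

`cardiokit` implements an end-to-end pipeline for screening cardiac health
from two kinds of input: a single-lead ECG signal (beat detection, interval
features, rule-based beat labels) and a tabular clinical dataset (row
completeness filtering, stepwise predictor selection). Downstream, a common
evaluation harness scores classifiers with a ten-metric suite and a
binary-entropy uncertainty measure. This note records the models, the
parameters that matter, the numerical choices, and the known limits of what
the synthetic studies demonstrate.

## Signal model and preprocessing

The ECG is treated as a uniformly sampled voltage series `x(i)` at sampling
frequency `fs` (default 360 Hz). Preprocessing is three linear steps:

1. **Normalization** to [−1, 1]:
   `x̄(i) = 2·(x(i) − min x)/(max x − min x) − 1`.
   This removes the DC offset and inter-record amplitude variance. A
   constant record has no amplitude range and is rejected. Note that after
   the subsequent high-pass the *isoelectric baseline* of a normalized
   record sits below zero (the filter removes the mean, and ECG waves are
   predominantly one-sided); the fiducial stage therefore never assumes the
   baseline is at zero.
2. **Baseline-wander removal**: linear-phase FIR high-pass, Hamming window,
   cutoff 0.5 Hz (respiration and electrode motion live below ~0.5 Hz).
   The tap count follows the 3·fs/cutoff transition rule, forced odd, and
   is capped for short inputs so the forward–backward padding fits.
3. **Powerline removal**: IIR notch at 50 Hz (config-overridable to 60 Hz),
   quality factor 30 (≈1.7 Hz −3 dB width at 50 Hz).

Both filters are applied forward–backward (zero phase): interval features
are timing-sensitive, and a causal filter would shift every fiducial by its
group delay. Filtering preserves length, sampling rate, and linearity to
numerical precision.

## R-peak detection

Detection must be invariant to lead polarity: a QRS complex can point
downward, and the classical slope-amplitude detector chain handles this
naturally because its squaring stage discards sign. The stages are:

bandpass (5–15 Hz FIR) → derivative → squaring → moving-window integration
(0.150 s). The result is a nonnegative *envelope* whose local maxima mark
QRS complexes.

Envelope peaks are split into signal and noise clusters by an **exact 1-D
two-means partition**: the optimal 2-means split of scalars is a split of
the sorted values, found by an O(n) prefix-sum scan over all split points
(deterministic — no RNG, no iterative seeding, always the global optimum).
The acceptance threshold is the midpoint between the cluster boundaries,

    th = (max(w0) + min(w1)) / 2 ,

where `w0` holds the low-amplitude (noise) peaks and `w1` the QRS peaks.

Within each accepted envelope region the R-peak is localized on the
*original* signal. First the signal's strict local extrema are extracted
(plateaus represented by their first sample; the sequence strictly
alternates maxima/minima by construction). Low-persistence wiggles are then
cancelled by **LMMD** (local maxima/minima difference cancellation): the
adjacent max/min pair with the smallest amplitude difference is removed
repeatedly until every remaining adjacent pair differs by at least a
persistence threshold, itself set by the same two-means split applied to
the adjacent-pair differences. Removal of an adjacent pair preserves
alternation, so what survives are the prominent deflections of either
polarity; the R-peak is the surviving extremum of largest |amplitude| in
the region (ties go to the earlier sample). A 0.2 s refractory period
suppresses the weaker of two nearby candidates.

**Search-back.** A beat whose envelope peak misses the threshold — the
typical case is a premature ventricular beat, whose wide, low-slope QRS
carries little 5–15 Hz slope energy — leaves an RR gap much longer than its
neighbours. Each gap longer than 1.5× the median RR is re-scanned once: the
strongest remaining envelope peak inside it is localized, and the beat is
accepted only if its signal |amplitude| is at least half the median
|amplitude| of the already-accepted R peaks. The amplitude-domain check is
what keeps T waves and noise out; an envelope-domain second threshold
cannot work here because the wide QRS's envelope peak is often *below* the
noise cluster.

Every stage is linear, sign-free, or |amplitude|-driven, so
`detect(x)` and `detect(−x)` return identical indices — property-tested
exactly on noise-free records.

## Fiducials and interval features

Each detected beat is analysed in a fixed window of 200 samples with 75
left of R (≈0.56 s at 360 Hz, ≈0.21 s of atrial context). Q and S are the
extreme values just left and right of R — minima for upright beats, maxima
for inverted ones — within a ±0.15 s radius. The radius must exceed half
the widest QRS the rules need to measure: with a 0.10 s radius the
measurable QRS saturates at 0.20 s, exactly the premature-ventricular
boundary, and the rule could never fire. 0.15 s supports QRS up to 0.30 s.

P and T are searched outside a 20 ms guard band around the QRS: P in
[window start, Q−guard], T in [S+guard, window stop). The winning extremum
is the largest *in the R wave's polarity direction* — on a clean beat this
equals the largest-|amplitude| extremum, but it is robust to the
opposite-sign undershoot a high-pass filter leaves around a large QRS, and
it keeps inverted records on the same indices. A peak below 2% of |R| is
reported absent rather than invented.

P/T localization and width measurement run on a ~20 ms zero-phase
moving-average smoothed copy of the signal (QRS measurements stay on the
raw samples): P and T are low-frequency waves, and sample-level noise
otherwise corrupts the half-amplitude crossings. Wave widths are full
widths at half maximum, measured against a *local isoelectric reference* —
the 25th percentile of the directed amplitude over the adjacent inter-wave
segment (PQ segment for P, ST segment for T). A global zero reference is
wrong after mean-removing filters; the window median is wrong because the
broad T wave dominates it.

The per-beat feature matrix ("fpi") carries six durations in seconds:

| feature | definition | generator default |
|---|---|---|
| RR  | r_i − r_{i−1}, from the second beat | 60/heart-rate |
| QRS | S − Q | 0.10 s |
| QT  | Q to T offset (half-amplitude decay after T) | 0.40 s |
| PR  | P peak to R peak | 0.16 s |
| P   | P-wave FWHM | 0.09 s |
| T   | T-wave FWHM | 0.16 s |

QT ends at the T *offset* because the 0.44 s clinical bound is defined to
the end of repolarization, and PR is peak-to-peak because that is how the
beat rules state it. Absent P/T propagate missing values; beats whose
window crosses a record edge are skipped with a warning, not padded. On
noise-free synthetic records the pipeline recovers RR exactly and
QRS/QT/PR within ±0.02 s for ≥99% of beats.

## Beat behaviour rules

Each beat is labelled by clinical range rules, checked in the order
arrhythmic > abnormal > normal (the rhythm-level rules take precedence
because the procedure exists to isolate arrhythmic beats, and the PVC rule
is a joint condition):

* **arrhythmic** — RR > 1.2 s (strict), or QRS > 0.20 s together with an
  irregular RR (current RR deviating >20% from the median of the recent RR
  window: the premature-ventricular pattern);
* **abnormal** — QRS outside [0.12, 0.20] s (inclusive), QT ≥ 0.44 s
  (the bound itself violates "less than"), or PR outside [0.12, 0.20] s;
* **normal** — no rule fired.

A beat with no measurable feature at all is an error, not a silent label.
The first beat of a record has no RR and is judged on the remaining rules.

Per-record detection quality is summarized from total beats N, correctly
identified beats CB and missed beats NMB as SE% = 100·CB/N,
ACC% = 100·(CB−NMB)/N and DER% = 100·(2·NMB)/N — each missed beat counts
once as a false negative and once as a false positive, the only reading
that reproduces the published worked rows. Reporting uses half-even
rounding to 2 decimals; a few published rows appear truncated instead, and
only rows where both conventions agree are asserted.

## Clinical tables and stepwise selection

Rows with any missing cell (empty or `?`, the Cleveland convention) are
excluded before modelling; the canonical 303-row table with 33 incomplete
rows reduces to 270. Attribute identifiers are assigned deterministically
in sorted name order.

Predictor selection is classical stepwise regression on OLS fits: forward
entry of the candidate with the smallest partial-F p-value when it beats
p_enter = 0.05, then backward elimination of the worst included predictor
while its p-value exceeds p_exit = 0.10. For single-term moves the
partial-F test equals the squared-t test of that coefficient in the larger
model, which is how it is computed (statsmodels OLS). The 0/1 outcome is
fitted by least squares — partial-F p-values are defined for nested linear
models, and 0.10 as exit tolerance is consistent with published selections
retaining a p = 0.091 attribute. Ties break by attribute name; columns are
pre-sorted, so the result is invariant to input column order. Perfectly
collinear designs are rejected by a rank check naming the columns.

**Operating characteristics.** With effects ≥5 standard errors the
procedure recovers every true predictor essentially always (recall ≈100%
over seeded replicates). It is *not* a family-wise-controlled procedure:
each forward pass tests k candidates at level α, so with pure-noise
predictors the final model is empty with probability ≈(1−α)^k — about 77%
for five candidates at α = 0.05, about 51% for a 13-attribute table. The
acceptance suite keeps a stricter (≥90%) bound on the five-candidate
pure-noise study as a red marker of this structural property rather than
weakening the check; exact-set recovery (~80% with four noise candidates)
is reported alongside recall for the same reason.

## Classifier harness, metrics, entropy

Five standard classifiers are delegated to scikit-learn: k-nearest
neighbours (k = 5), a multilayer perceptron with three tanh hidden layers
of seven neurons (five layers counting input and output), an RBF-kernel
SVM, a random forest (100 trees), and Gaussian naive Bayes. The distance-
and gradient-based learners (knn, svm, nn) run inside a standardization
pipeline — clinical attributes mix values in the hundreds with 0/1 flags
and those learners are not scale-invariant; trees and naive Bayes run on
raw features. Evaluation is a stratified 80/20 split with pooled held-out
confusion counts, plus stratified 10-fold cross-validation reported
alongside; every source of randomness is seeded, and repeated runs are
bit-identical. Multi-class beat labels are pooled one-vs-rest into a
single confusion-count object.

The metric suite follows the conventions of the source tables exactly,
including two idiosyncratic definitions kept under their table names:

* `AUC = (Se + Sp)/2` — this is *balanced accuracy*, not ROC area; a
  conventional ROC AUC is available separately (`roc_auc`) and is never
  used in table arithmetic;
* `G-mean = sqrt(precision·recall)` — the precision–recall convention, not
  sqrt(Se·Sp).

The remaining metrics (ACC, Prec, Se, Sp, F1, MCC, FPR, DER) are standard.
Undefined ratios (zero denominators) are reported as missing, never 0.

Cross-dataset summary arithmetic is element-wise: the average table is the
mean of the two per-dataset metric vectors, and the difference-ratio table
is 1 − average (each metric's shortfall from a perfect score). Classifier
uncertainty is the binary information entropy of a performance fraction,

    H(p) = −p·log2 p − (1−p)·log2(1−p)   bits,  0·log2 0 ≡ 0,

maximal (1 bit) at p = 0.5 and zero at certainty; it is symmetric and
concave, which the tests verify against an independent high-precision
oracle. The published per-metric entropy table is *not* consistently the
binary entropy of the published average table (several cells disagree with
the formula applied to their own inputs); this package implements the
formula as printed and reports what it computes. The bundled per-dataset
metric tables and per-record beat counts (`cardiokit.reported`) are
worked-example *inputs*: reproducing their absolute values would require
the external recordings and unreported training details, which is out of
scope.

## Synthetic data generator

The ECG generator is deliberately parametric rather than a dynamical
simulator: each beat is a piecewise-linear (triangular) QRS plus Gaussian
P and T bumps placed on an RR schedule, so every fiducial index and
interval is known *exactly* by construction. Defaults: R amplitude 1.0,
Q/S −0.15, P 0.15 with 0.09 s FWHM, T 0.30 with 0.16 s FWHM, QRS base
0.10 s, PR 0.16 s, QT 0.40 s. Wave "widths" are FWHM, matching the
extractor's half-amplitude convention. Noise reproduces the three
artefacts of ambulatory recording: baseline wander (0.1 @ 0.3 Hz,
respiration), powerline pickup (0.05 @ 50 Hz) and white noise (σ = 0.02),
all seeded and reproducible. Anomaly plans plant long-RR beats and
wide-QRS premature beats at chosen positions; ground-truth labels are
produced by running the rule engine on the *programmed* intervals, so
record and labels are consistent by construction and independent of any
detector. P/T waves of adjacent beats may overlap additively at high heart
rate (as in real ECG); the generator errors only if QRS complexes would
collide (RR < QRS base + 50 ms).

The clinical generator emulates a 13-attribute heart-disease table with
attributes drawn inside their conventional value sets, a binary outcome
from a linear score over a known informative subset (plus Gaussian noise,
σ = 0.5, threshold at zero), and a chosen number of rows with planted
missing cells. A separate Gaussian linear-model generator
(`synth_linear_table`, three true effects ≥5 SE plus four noise
predictors by default) drives the stepwise power studies.

**What passing these studies does and does not show.** The synthetic
morphology has exact, stationary waveshapes, stationary noise, and no
ectopic morphology change beyond QRS width — so the detection and interval
results demonstrate correctness of the algorithms under controlled
conditions, not clinical-grade performance on ambulatory recordings with
electrode motion, waveform variability, or fibrillation (explicitly out of
scope). Likewise the clinical generator's linear outcome mechanism favours
linear selection; it validates the selector's mechanics, not its adequacy
for arbitrary epidemiological data.

## Problem sizes

The bundled studies use 30 s records at 360 Hz (100 seeded records for the
detection study, spanning 40–180 bpm with mixed polarity), a 60 s record
for interval recovery, 100 seeded replicates for each stepwise study, and
a 303-row clinical table; these sizes give stable rates while keeping the
full suite fast to run.
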