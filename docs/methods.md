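# Methods

## Problem and approach

Long-term (≥ 24 h) single-lead ambulatory ECGs produce beat streams far too
long for manual atrial-fibrillation (AF) review. After QRS detection and
rhythm adjudication, all that remains of each recording is a sequence of
R-wave times and per-beat rhythm labels. `lorenzaf` detects AF episodes from
that reduced representation alone, exploiting the nonlinear structure of the
RR-interval series: plotting consecutive interval pairs (RR_n, RR_{n+1})
yields a Lorenz scattergram (Poincaré plot) in which sinus rhythm collapses
to a tight cluster on the identity line (successive intervals nearly equal),
AF spreads into a diffuse fan (successive intervals serially uncorrelated —
"irregularly irregular"), and ectopy throws points into off-diagonal lobes
(short coupling interval followed by a compensatory pause).

The processing chain is:

1. **Windowing.** The beat stream is cut into windows of 85 R waves. For
   training-data augmentation the window slides by 9 beats (overlapping
   windows); for calibration, evaluation and deployment, windows are
   non-overlapping (step 85). Trailing beats that cannot fill a whole
   window are dropped.
2. **Window labeling (30-s rule).** A window is AF if it contains a maximal
   run of consecutive AF-labeled beats spanning ≥ 30 s, measured from the
   first to the last beat of the run; otherwise non-AF. The threshold is
   inclusive at exactly 30.0 s, and two AF runs separated by even a single
   non-AF beat are judged separately. This is the clinically conventional
   minimum-duration criterion for calling an AF episode.
3. **Rasterization.** Each window's 84 intervals give 83 points
   (RR_n, RR_{n+1}), binned into a 32×32 grid over a fixed axis range of
   [0, 2] s per axis (linear bins, index = floor, out-of-range values
   clamped into the edge bins). Every non-binarized grid therefore sums to
   exactly 83 — a conservation law the test suite exploits. A fixed axis
   range keeps attractor geometry comparable across records; an adaptive
   range would rescale every image differently. Cell values are point
   counts; the classifier consumes counts divided by the per-image maximum
   (a binary-occupancy mode exists behind `RasterSpec.binarize`).
4. **Classification.** A compact CNN maps each image to an AF probability.
5. **Aggregation.** A record's *AF burden* is the fraction of its
   non-overlapping windows classified AF at the image cutoff; two further
   cutoffs on the burden give the three-way diagnosis
   (non-AF / paroxysmal AF / persistent AF).

## Classifier

The network is the smallest conventional three-stage convolutional stack
for 32×32 inputs: three rounds of (3×3 same-padding convolution → ReLU →
2×2 max pooling) with 16/32/64 filters, flatten, a 64-unit ReLU dense
layer, and a single sigmoid output — 88,961 parameters. Training uses
binary cross-entropy and Adam (lr 1e-3, β = 0.9/0.999), batch size 128,
and a fixed budget of 20 epochs with no early stopping (accuracy and loss
plateau well before that on the synthetic task; a fixed budget also makes
runs comparable). Optional inverse-frequency class weighting exists for
badly skewed cohorts and is off by default (the default synthetic cohort
is ~50/50).

The CNN is implemented directly on NumPy: im2col lowers each convolution to
one BLAS matrix multiply, backward passes are hand-derived (checked against
central finite differences in the suite), and weights are He-initialized
from a seeded generator. This keeps the package dependency-light and makes
an entire training run an exact, bit-reproducible function of the seed on a
given platform. Float32 is used throughout.

## Threshold calibration

Three cutoffs are calibrated, each by maximizing the Youden index
J = sensitivity + specificity − 1 over a ROC curve:

1. **Image cutoff** — ROC of image probabilities vs. image labels over the
   development pool.
2. **Record-AF cutoff** — ROC of record burdens (computed at the image
   cutoff on non-overlapping windows) vs. AF-vs-non-AF record truth.
3. **Persistent cutoff** — the same burdens restricted to AF records,
   persistent vs. paroxysmal.

ROC thresholds are the distinct observed scores plus a sentinel one unit
above the maximum (the all-negative operating point); the AUC is the
trapezoidal area, equal to the tie-adjusted pairwise-comparison
probability. Ties on the maximal J are resolved toward the **higher**
threshold (the more specific cutoff), using a 1e-12 float tolerance so that
rounding noise cannot flip the tie direction. The decision intervals are
half-open: burden ≥ record-AF cutoff means AF, burden ≥ persistent cutoff
means persistent. If the two record-level calibrations cross, the record-AF
cutoff is clipped down to the persistent cutoff to preserve the ordering
invariant.

The burden-fraction aggregation is a deliberate design choice: published
operating points for record-level AF calls sit near 0 ("any appreciable
burden means the record has AF") and near 1 ("almost every window AF means
persistent"), which is only coherent for a fraction. A mean-raw-score
alternative is available via `RecordAggregation.MEAN_SCORE`.

## Synthetic cohort

Real adjudicated Holter databases cannot ship with a package, so the
generators produce beat streams with the statistical structure that drives
the scattergram classes, with known beat- and record-level truth:

| parameter | default | meaning |
|---|---|---|
| `duration_s` | 3600 s | record length (1 h) |
| `mean_rr_s` | 0.8 s | mean RR (75 bpm) |
| `sinus_sd_s` | 0.02 s | white beat-to-beat jitter (sinus) |
| `resp_freq_hz` | 0.2 Hz | respiratory modulation (12 breaths/min) |
| `resp_amp_s` | 0.05 s | respiratory RR amplitude |
| `af_cv` | 0.24 | coefficient of variation of AF RR |
| `episode_mean_af_s` | 300 s | mean AF dwell (paroxysmal) |
| `episode_mean_sinus_s` | 300 s | mean sinus dwell (paroxysmal) |
| `pvc_rate_per_min` | 2 | premature-beat rate on non-AF records |
| `prematurity_fraction` | 0.4 | how early the ectopic beat falls |

Sinus RR is a respiratory sinusoid plus Gaussian jitter; its lag-1
autocorrelation has the closed form cos(2π·f·RR̄)·σ²_sin/(σ²_sin+σ²_noise),
≈ 0.41 at defaults, and the tests verify simulation against that formula.
AF RR is i.i.d. log-normal with the configured mean and CV — any
serially-uncorrelated positive distribution reproduces the fan attractor;
one is fixed and documented. Paroxysmal records follow an alternating
renewal process with exponential dwells (episode boundaries are kept on the
record for audit). Ectopy shifts Poisson-sampled beats early by a fraction
of their RR, which automatically extends the following interval
(compensatory pause, two-beat sum preserved); ectopic beats keep their
underlying rhythm label, so the classifier must learn not to call them AF.
All RR values are clipped to [0.3, 2.0] s, the rasterizer's axis range.
The class-separability invariant — mean sinus lag-1 autocorrelation exceeds
the AF value by ≥ 0.3 at defaults — is asserted in the suite; it is what
makes the image classes learnable at all.

What the generators do *not* emulate: real QRS-detector noise and missed
beats, atrial flutter's organized sawtooth RR patterns, sick-sinus and
paced rhythms, circadian rate drift, or signal-quality dropouts. Passing
the synthetic recovery test therefore demonstrates that the pipeline's
machinery (windowing, labeling, rasterization, training, calibration,
aggregation) is correct and self-consistent — not that the trained weights
transfer to clinical data, which requires the real adjudicated databases.

## Evaluation protocol and problem sizes

`run_pipeline` uses two cohorts sharing one global seed: a *development*
cohort (default 10 records per class, 1-h records) that supplies augmented
training images, a 9:1 image-level train/validation split, and all three
calibrations; and a separately seeded *evaluation* cohort scored with
non-overlapping windows only — the deployment setting — from which the
two-level report is computed. At these sizes a full run is ~14,700 training
images and ~1,600 evaluation images and takes a few minutes on one CPU
core; the sizes were chosen so that a complete train-calibrate-evaluate
cycle is a routine desk-scale experiment. Record-level reports are
one-vs-rest per class; likelihood ratios with zero denominators are
reported as an explicit NA, which genuinely occurs when a class is
perfectly separated.

The 9:1 split is at image level; with overlapping windows this lets near
-duplicate images of one record land on both sides, so validation accuracy
overstates generalization. The held-out evaluation cohort exists precisely
to close that gap; a record-level split can be had by building images per
record and splitting record ids before pooling.

## Numerical and degenerate-input choices

* Binning: `index = floor((RR − rr_min)/(rr_max − rr_min) · 32)`, clamped
  to [0, 31]; an RR exactly at `rr_max` lands in the last bin.
* Empty or single-beat records, windows shorter than 85 beats, records
  below one window, single-class training sets, and single-class ROC
  inputs are all hard errors with named messages, not silent degradations.
* Unknown rhythm codes map to non-AF with a logged warning (only
  AF-family codes are positive), matching the binary labeling convention
  in which flutter, tachycardia, ectopy and paced rhythm are all non-AF.
* RRI TSV files print times to 6 decimals; round-tripping preserves beat
  times to 1e-6 s and labels exactly.
* Determinism: every stochastic stage (simulation, split, init, batch
  shuffling) draws from generators seeded via `SeedSequence` spawning from
  the single pipeline seed; training itself is plain float32 NumPy, so a
  rerun reproduces thresholds and metrics exactly on the same platform.

## Known limitations

* The exact published network architecture for this task is not public;
  the stack above is the smallest conventional choice consistent with
  three convolution layers on 32×32 inputs, and every dimension is
  exposed in `ModelConfig`.
* The scattergram axis range and pixel semantics (counts vs. binary) are
  likewise undocumented upstream; both are explicit `RasterSpec` choices.
* Beat-level AF labels are assumed adjudicated and reliable; the package
  performs no signal-quality triage, filtering, or QRS detection.
* Thresholds calibrated on the synthetic cohort are meaningful only for
  that cohort; clinical use requires recalibration on adjudicated data.
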