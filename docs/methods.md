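# Methods notes

## Signal model and feature definitions

The pipeline assumes a single bipolar occipital EEG channel (µV) and a
head-mounted three-axis gyroscope (unitless device readings), both sampled
at 128 Hz and already conditioned by the acquisition hardware. Analysis
operates on contiguous, non-overlapping 2-s epochs aligned to sample 0 —
the natural framing for a streaming on-chip implementation — with any
trailing partial epoch dropped (logged, never an error).

**Band power.** Power in band *i* is the sum of squared one-sided DFT
magnitudes over the 0.5 Hz bins whose center frequency falls in the band.
The rectangular window (no taper) and the missing ×2 one-sided energy
correction are deliberate: relative band power is a ratio of band powers
from the same spectrum, so any common scaling cancels. The band partition
is θ [4, 8), α [8, 13), β [13, 30] Hz — half-open on the left two bands so
the denominator of RBP counts every 4–30 Hz bin exactly once. (Common
verbal definitions leave a gap between a θ that ends at 7 Hz and an α that
starts at 8 Hz, and double-book 13 Hz; a partition is required for the
ratio to be well defined.)

**Movement power.** MP is the population standard deviation (divide by
N), within the epoch, of the per-sample mean of the three gyro axes. The
population convention is fixed for reproducibility; at N = 256 the
sample/population difference is ~0.2 %. MP is invariant to per-axis
constant offsets (gyro bias) and scales linearly with overall gain, so it
is used only comparatively, in device units.

**Windows.** Thirty consecutive epoch feature vectors are averaged
(component-wise arithmetic mean) into one 1-minute window carrying that
minute's video-scored label. Epochs with zero in-band power are flagged
degenerate and left out of their window's mean; a window more than half
degenerate is emitted but marked excluded so NaNs never propagate.

## Filtering

The EEG conditioning chain is a 2nd-order Butterworth high-pass at 4 Hz
cascaded with a 4th-order Butterworth low-pass at 30 Hz — the same orders
as the analog front end the pipeline emulates — applied causally
(forward-only, zero initial state), since zero-phase filtering is
unrealizable in a real-time system. A 60 Hz notch (Q = 30) is available
but off by default: a car has no mains power, and the notch is only
needed for indoor recordings. Gyro channels are never filtered; the
sensor conditions its own output.

The high-pass startup transient decays within well under one 2-s epoch,
so transient epochs are kept by default; a configurable drop is available
but changes the exact window bookkeeping and is therefore off.

## Classification

Soft-margin SVM (libsvm via scikit-learn, fixed tolerance 1e-3, bounded
iterations, inputs sorted by subject and window index for deterministic
fits). The RBF kernel is parameterized by its radius g, with gamma =
1/(2g²) passed to the solver, so the hyperparameter grid is expressed in
g. Features are standardized with an affine transform fitted on the
training fold only and stored inside the model — RBP (percent, ~15–45)
and MP (device units, ~50–600) are on incompatible scales for an RBF
distance. Decision values of exactly zero map to +1 (drowsy): the
fail-safe direction for a safety application.

Evaluation is leave-one-subject-out: pooled (count-weighted) confusion
over all held-out windows, which is the only aggregation under which
Accuracy, Sensitivity and Specificity remain mutually consistent at
unbalanced class sizes. Grid search is exhaustive with ties broken toward
the smallest C, then the smallest g. The default grids are logarithmic
with ~7 points per axis over [0.01, 10]; the full 0.01:0.01:10 sweep
(10⁶ RBF points) is available via `full_grid()` with a cost warning.

ROC areas are computed from midranks (exactly the Mann–Whitney pairwise
count, ties at ½) and folded to max(A, 1−A): θ share discriminates
*downward* (lower when drowsy), so the folded value keeps the headline
number in [0.5, 1] while raw value and orientation are always reported.

## Synthetic cohort: what it emulates

The generator emulates a six-subject, one-hour monotonous-driving
experiment with per-minute ground truth. Defaults are the stated world:
per-state feature medians (alert RBP 18.2/37.9/38.6 %, MP 74.1; slightly
drowsy 14.5/42.6/37.9 %, MP 168.7), class balance 68 alert / 198 slightly
drowsy / 94 mid-or-late minutes of 360 (cohort totals exact by
construction), monotone per-subject vigilance trajectories, and
movement-artifact corruption of EEG during drowsy-minute bursts.

Stored RBP targets are the printed medians, which sum to ~95 rather than
100 (medians of ratios need not close); they are normalized to a simplex
for calibration. This shifts each calibrated component ≤ 2.2 percentage
points from its printed value, inside the ±3 pp recovery tolerance.

**EEG.** Per minute, EEG is a sum of three band-limited noise components
(white noise through 4th-order Butterworth band-pass filters, unit
variance). Component variances are solved per minute from a 3×3 linear
system whose coefficients are the *expected measured* band powers of each
component — computed analytically in the lag domain, so that rectangular-
window spectral leakage of the 2-s DFT (which otherwise inflates the wide
β band by ~2 pp) is accounted for exactly — with the expected artifact
contribution subtracted from each band's target. A solution that would
need negative variance by more than 5 % of total power raises a profile
error (unsatisfiable targets, e.g. excessive artifact coupling); smaller
negative excursions from minute-level jitter draws are clipped to zero.
Total in-band power is set so EEG amplitude sits near 20 µV sd (the
10–100 µV physiological range); samples are clipped at ±200 µV.

**Gyro.** White jitter calibrated so epoch MP averages the alert target.
Slightly-drowsy (and mid/late) minutes add 1–3 s unit-peak Gaussian
angular-rate pulses (yaw on X with probability 0.5, shake on Y and sway
on Z with 0.25 each; at least one per minute, Poisson rate 5/min), scaled
by a per-minute Brent solve so the 30-epoch window MP hits the drowsy
target. With `burst_rate=0` no bursts are placed and drowsy minutes stay
at baseline MP — bursts *are* the movement signature, so removing them
removes the signal (used by the chance-level test).

**Artifact coupling.** EEG receives additive broadband noise scaled by
instantaneous gyro magnitude (default 0.005 µV per device unit). During a
burst this injects white power comparable to the neural signal, which
mechanically raises the measured β share and dilutes α in burst epochs —
the dry-electrode friction signature — without modeling electrode
physics.

**Dispersion.** Medians constrain location only, so spread is a free
choice, fixed once: per-subject target jitter (RBP sd 2.5 pp additive,
renormalized; MP lognormal σ 0.12) and minute-to-minute vigilance jitter
(RBP sd 4 pp; MP lognormal σ 0.15). These values were chosen so the
single-feature ROC areas land in the reported qualitative regime — EEG
features weakly separable (~0.5–0.8), MP strongly separable — rather than
the near-perfect separation a location-only simulator produces.

**Randomness.** All draws flow from one integer seed through a
per-subject `default_rng([seed, subject_index])` stream, so any single
session is reproducible independent of cohort order.

## What a green test does and does not establish

The simulator reproduces the *distributional* structure of the
experiment: state-conditional medians, class balance, artifact direction,
and the qualitative ordering MP > EEG in both ROC area and LOSO accuracy.
It does not reproduce real EEG morphology (no 1/f background outside
4–30 Hz, no eye blinks, no electrode pops), real head-movement kinematics,
or between-subject physiological diversity beyond scalar target jitter.
Consequently the synthetic LOSO accuracies (hybrid ≈ 99 %) exceed what
real recordings support (mid-90s), and green calibration tests establish
pipeline correctness — not field performance of the detector.

## Numerical choices and degenerate inputs

- Sessions shorter than one epoch segment to an empty list, not an error.
- Degenerate (zero-power) epochs are excluded from window means; fully
  degenerate windows carry NaN features and an excluded label.
- Sens/Spec with an absent class return NaN with a warning.
- Confusion reconstruction from printed percentages warns when no integer
  pre-image reproduces the inputs at 2-decimal precision.
- LOSO folds whose training data collapse to one class are recorded as
  fold errors and left out of pooling rather than aborting the run.
- CSV floats are written at %.10g, making repeated runs byte-identical.

## Known limitations

- The full 10⁶-point hyperparameter sweep is impractical at desk scale;
  default grids subsample it logarithmically.
- MP-only classification on the synthetic cohort is nearly perfect, so
  the hybrid-vs-MP margin is compressed relative to real data, where EEG
  contributes complementary information during still drowsiness.
- The generator's mid/late-stage minutes reuse the slightly-drowsy
  signal model; they exist only to be excluded, as in the study design.
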