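# Methods

## Overview

`accelcal` calibrates accelerometer intensity cut-points against indirect
calorimetry and validates them externally. The unit of analysis is the 5 s
epoch of an acceleration metric (ENMO in milli-g, or activity counts),
labelled with the intensity class of its parent activity bout as measured
by gas exchange. ROC analysis over pooled epochs yields one threshold per
(wear site × metric × boundary), where the boundaries are
sedentary-to-light (ST, ≤ 1.5 METs) and light-to-MVPA (≥ 3 METs).

## Acceleration metrics

**ENMO.** Per sample `e = max(√(x² + y² + z²) − 1, 0)` (truncation before
averaging, matching the raw-data toolchain definition), averaged per
second and expressed in mg, then averaged over 5 s epochs. ENMO is
rotation-invariant and needs no filtering.

**Activity counts.** The vendor algorithm is proprietary; we implement the
published open-source reconstruction shape: linear-interpolation resample
to 30 Hz, order-3 Butterworth band-pass 0.25–2.5 Hz (coefficients are
module constants; the filter is initialized in the steady state of a
constant input so static gravity produces no start-up transient), clip to
±2.13 g, quantize at 1/256 g, rectify, zero values below the 0.068 g
dead-band, decimate to 10 Hz by running maxima, sum per second per axis;
the per-second vector magnitude is rounded to an integer and summed over
the epoch. Bit-identity with vendor software is not claimed and counts are
reported in quantization units, so absolute magnitudes differ from
vendor-scaled counts by a constant factor; all within-pipeline comparisons
are unaffected.

**Analysis windows.** The first and last 15 s of each bout are discarded
for stability and the remainder is capped at a centred 180 s window
aligned to whole epochs (the "about 3 min" convention). Bouts too short to
yield one epoch after trimming are excluded. Second boundaries follow the
signal's own sample grid; epochs start at the window start.

## Calorimetry

Breath values land in their floor second; seconds with several breaths
take the mean; empty seconds carry the last value forward at most 10 s
(longer gaps stay missing). Artifact peaks deviating more than 2 SD from
the whole-window mean are removed in a single pass (two-sided by default,
since dropouts are as unphysiological as spikes; one-sided and iterated
variants are flags). METs = mean cleaned VO2 over the last 2 min of the
bout / body mass / 2.8 mL/kg/min (the older-adult 1-MET value; 3.5 is
available by configuration). Bouts with fewer than 30 usable seconds are
flagged unusable and excluded. The resting rate is the mean cleaned
VO2/kg over the last 5 min of the lying-still bout. Classes are assigned
at the activity level (every epoch inherits its bout's class), with both
boundaries inclusive (1.5 → ST, 3.0 → MVPA).

## ROC calibration

Candidate thresholds are midpoints between consecutive distinct metric
values plus the infinite ends. Direction convention (not derivable from
threshold tables alone, so fixed here and stored with every cut-point):
ST is called when the value is *below* the ST threshold; MVPA when *at or
above* the MVPA threshold. AUC is the trapezoid area integrated in
threshold order, identical (to 1e-12, verified against a brute-force
pairwise oracle) to the Mann–Whitney concordance with ties counted 1/2.
Variance, 95% CIs and two-curve comparisons use DeLong structural
components with a normal approximation; paired comparisons require curves
built from the same epochs in the same order. Epochs are pooled across
participants into a single ROC (no clustering adjustment), so the CIs are
conditional on the pooled sample. The operating point minimizes
`(1 − sens)² + (1 − spec)²`; ties (to 1e-12) resolve toward higher
specificity, then the smaller threshold — specificity is privileged
because misclassifying light activity as the behaviour of interest is the
costlier error here. Thresholds are reported as integers in native units;
the raw threshold is retained and is what cross-validation applies, so
re-applying a bundle to its own calibration sample reproduces the recorded
sensitivity/specificity exactly.

## Cross-validation and scale conversion

Fixed thresholds are applied, with the same direction convention, to an
independently generated arm; a value exactly at an ST threshold is *not*
sedentary and exactly at an MVPA threshold *is* MVPA. Count thresholds
convert between epoch lengths as `t × b / a`, rounded (counts are sums);
ENMO thresholds are epoch-length-invariant (averages) and conversion is
refused with an explanatory error. No sampling-rate correction is applied
between the 80 Hz and 60 Hz arms: both are resampled to 30 Hz before
counting, and rate effects matter mainly at intensities these cohorts do
not reach.

## Synthetic data generator

The generator emulates the statistical shape the analysis assumes, not
physiology in detail. Per bout the raw signal is a fixed random unit
gravity vector plus a single sinusoid at the activity's dominant movement
frequency along a fixed random direction, plus white jitter (0.002 g per
axis). The sinusoid amplitude is found by bisection so that the bout's
mean ENMO matches the activity's per-site target (monotone in amplitude;
simulated over whole cycles with a frozen jitter realization; tolerance
2%). Quiet postures use a 0.1 Hz sway frequency, below the counts
pass-band, so stillness yields zero counts as in real devices.

Breath series have exponential inter-breath gaps clipped to 1.5–6 s
(~12–30 breaths/min). VO2 follows each bout's steady state
`MET × 2.8 × mass` through a first-order on-transient (τ = 30 s) with 4%
multiplicative Gaussian noise; a configurable fraction of breaths (5% by
default) is replaced by spikes several SD above the local level. The
lying-still bout's intensity is tied to the participant's individual
resting VO2 (3.0 ± 0.7 mL/kg/min across participants) so the resting-rate
analysis has a recoverable truth.

Between-participant variability enters by drawing each participant's bout
METs and per-site ENMO targets from the template means/SDs (truncated at
0.5 mg and 0.7 METs). Calibration-arm ENMO means and SDs are the published
laboratory values for this population; per-activity MET means are
generator configuration because only a distribution plot of them is
published. Our choices: lying = resting (≈1.07), sitting tasks 1.15–1.35,
quiet standing 1.45 (under an energy-expenditure-only criterion quiet
standing in this age group sits at the sedentary boundary), standing
chores 2.0–2.8, treadmill walking at 1.5 mph 2.8, over-ground walks
3.3–3.9. The cross-validation arm has no published acceleration table, so
all nine activity targets there are configuration, chosen once for a
70-plus cohort doing household tasks and as-fast-as-possible walks, with
clear separation between class means. A single documented seed (42)
defines the packaged demo dataset; identical seeds give byte-identical
outputs.

**What the generator does not emulate.** Movement is a pure tone along one
direction, so the counts dead-band (0.068 g) interacts with bout geometry
in an all-or-nothing way: when the movement direction is near-parallel to
gravity, a moderate-ENMO chore (~18 mg) needs only ~0.06 g of amplitude
and falls entirely below the dead-band on every axis, yielding exactly
zero counts — something broadband real movement at that intensity does
not do. In the packaged demo this caps the hip-counts sedentary
specificity near 0.80 on the cross-validation arm (one of sixteen
transfer values lands at 0.796; the rest are 0.85–1.00). There is no VO2
kinetics beyond the single exponential, no device miscalibration,
non-wear, posture information, or within-bout intensity drift, and bout
ENMO and MET draws are independent within an activity. Passing tests on
these data therefore demonstrate correctness of the analysis chain and
recoverability of known structure, not field validity of any particular
threshold.

## Problem sizes and runtime

The packaged demo uses 24 calibration and 12 cross-validation
participants, 3.5 min bouts (6.5 min lying; 5–6 min bouts in the
cross-validation arm), giving ≈36k calibration and ≈8k cross-validation
epochs; it completes in about ten seconds on one CPU. Statistical
calibration checks use 1000 simulations at n = 100/100 (DeLong CI
coverage 93–97%, paired type-I error 3–8% at α = 0.05). Parameter
recovery uses a three-activity protocol (class means 10/40/120 mg) at
three noise scales, with cut-points converging to the mid-gap boundaries
as noise vanishes.

## Known limitations

Pooled-epoch CIs ignore within-participant correlation (a per-participant
bootstrap is the natural extension). The counts reconstruction is a
documented surrogate, not the vendor algorithm. Generator realism is
deliberately minimal (see above); cut-points calibrated on synthetic data
are for validating the pipeline, not for field use.
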