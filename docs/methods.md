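# Methods

This note documents the models behind the two analysis arms and the design
choices made where the procedures left room — what the simulators emulate,
what they deliberately do not, and the numerical conventions of the
detection and decoding chains.

## Kinematic model

### Landmark-driven speed profiles

A trial's wrist speed profile is synthesised *from its target landmarks*
rather than from a fixed functional family. The acceleration trace is a pair
of beta-shaped lobes,

    a(t) ∝ u^p (1-u)^q,

one positive lobe on [0, T_peak_V] and one negative on [T_peak_V, Mov_T].
Given targets (Mov_T, T_peak_V, Amp_peak_V, T_peak_A, Amp_peak_A,
Amp_peak_D), the lobe peak positions and heights are fixed directly and each
lobe's sharpness is solved (Brent's method on the log area/height ratio) so
that the integrated speed reaches exactly Amp_peak_V at T_peak_V and returns
to zero at Mov_T. The symmetric minimum-jerk reach is the special case used
for the individual-condition baseline (D = 300 mm, MT = 700 ms): peak speed
1.875·D/MT at MT/2, acceleration extrema ±10·D/(√3·MT²) at
MT·(1/2 ∓ 1/(2√3)).

A plain (even skewed) minimum-jerk family has only two or three degrees of
freedom once the reach distance is fixed, so six independent condition
effects cannot be injected in it; landmark-driven synthesis makes every
tabulated effect an exact construction-time property. The price is that the
implied reach distance varies slightly with the landmarks (≈300 mm at the
defaults); distance is treated as emergent, not enforced.

The tabulated deceleration effect is applied to the *signed* deceleration
peak (social = individual + effect, with both values negative), so the
recovered signed difference equals the published table value by
construction.

### Grip aperture

Aperture opens from 10 mm (fingers opposed, markers on the nails) to 80 mm
at 60% of movement time and closes to 25 mm on the 20 mm sphere. Both
segments are quartic: zero velocity but *nonzero curvature* at the maximum
(so the detected aperture peak is a stable quadratic cap rather than a flat
plateau), and C² at contact. This matters because the detection thresholds
are small (±5 mm/s) relative to filter-scale ripple: a faster closing
geometry (e.g. 65 mm in ~0.21 s with minimum-jerk segments) leaves
post-contact aperture-velocity ripple of ~±11 mm/s after 10 Hz filtering,
which straddles the −5 mm/s end threshold and makes the detected movement
end bistable by ±80 ms. The default geometry keeps that ripple below
~3 mm/s.

### Calibration to the detection chain

Detected landmarks lag the physical profile: the speed needs ~10–20 ms to
climb through the 5 mm/s onset threshold, and the aperture velocity
re-crosses −5 mm/s a few ms before nominal contact. With `calibrate=True`
(default) each trial's profile is shifted, first using closed-form threshold
crossings of the continuous profile (inverse incomplete beta), then against
the actual filtered detection chain, until the detected Mov_T, T_peak_V and
T_peak_A equal the targets to within half a sample (the grid quantisation
floor at 140 Hz). Landmark sets on which the calibration cannot converge are
rejected and redrawn.

### Variability model

Three layers, all Gaussian on the landmark scale:

| layer | applied to | default basis |
|---|---|---|
| `between_subject_sd` | both conditions of a subject | plausible magnitudes (free parameters) |
| `effect_sd` | social condition only | set with `within_subject_sd` so that var(per-subject difference of 12-trial means) = effect_sd² + 2·within_sd²/12 matches the published SE-of-difference scale |
| `within_subject_sd` | every trial | ~4–10% of the landmark baseline |

Drawn landmark sets must stay in a plausibility band of profile-shape ratios
(acceleration-lobe area/height ratio c1 ∈ [0.40, 0.92] — minimum jerk sits
at 0.65; deceleration-lobe ratio c2 ∈ [0.22, 0.95]; relative acceleration
peak position m1 ∈ [0.20, 0.70]). Outside this band the speed rises so late
that the detected onset lags the movement by >100 ms — reaches no human
produces. The rejection sampling truncates the landmark distribution: at the
default SDs this shrinks the two large injected *amplitude* effect means by
roughly 10–15% (the deceleration baseline sits near the feasibility edge);
signs, time effects and the overall table structure are unaffected.

Marker noise defaults to 0.05 mm per axis (optical post-tracking precision).
After 10 Hz filtering and differentiation this leaves ~1 mm/s of velocity
noise — small relative to the ±5 mm/s thresholds, so the 500 ms dwell rules
remain stable.

What the generator does *not* emulate: marker dropout/occlusion, soft-tissue
artifact, the place phase after contact, curved transport paths, or any
correlation between kinematic and fMRI observables of the same subject.
Passing tests therefore certify the *processing chain*, not robustness to
those real-data features.

## Detection chain

* FIR low-pass: Kaiser window design, 10 Hz cutoff, 1 Hz transition band,
  50 dB ripple (413 taps at 140 Hz), applied zero-phase by reflect-padded
  convolution. The 50 dB spec (~0.3% ripple) keeps derivative-domain
  ringing well under the detection thresholds; trials must exceed the filter
  length (~3 s at default rest padding).
* Derivatives by central differences (one-sided at the ends); acceleration
  is the derivative of the scalar wrist speed, not the norm of the 3-D
  acceleration vector — only the former yields a signed deceleration peak.
* Dwell rules "longer than 500 ms" are implemented as ≥ 70 consecutive
  samples at 140 Hz (one-sample differences are below measurement
  resolution). Ties at extrema resolve to the earliest sample.
* Trials failing onset or end detection are flagged (`qc_flag`) and excluded
  from subject means; they are never silently dropped.

## Behavioral statistics

The Shapiro–Wilk gate (α = .05) is applied to the *paired differences* — the
quantity whose normality the paired t-test assumes. Wilcoxon W is the rank
sum of positive differences (zeros dropped, average ranks on ties; exact
null distribution when scipy can use it), so n = 23 all-positive pairs give
W = 276 and all-negative give 0. All p-values are two-sided. Effect size is
Cohen's d_z = mean difference / SD of differences; CIs are t-based for both
test kinds (for Wilcoxon rows they are descriptive, not rank-based).

## fMRI simulation

Per run, 50 balanced trials are scheduled with gaps = trial span (4 s:
reach-to-grasp, the 2 s inter-phase interval, and the start of the place
phase) + ISI, where ISI = 3 s + Exp(rate 0.5 s⁻¹) truncated at 8 s — a
right-skewed ("long exponential") distribution with most mass near the
minimum. A schedule whose last onset + 6 s exceeds the 495 s run raises
rather than silently clipping.

Each voxel's series is baseline + linear drift + slow sinusoid +
HRF-convolved trial responses + white Gaussian noise. The HRF is the
canonical double-gamma (peak delay 6 s, undershoot delay 16 s, ratio 1/6,
unit dispersion), normalised to peak 1; its argmax is ≈5 s and it is
negligible past 30 s. The per-trial response amplitude of voxel v is
`common_evoked + label · amplitude · w_v` with pattern weights w_v ~ N(0, 1)
drawn once per subject × ROI (stable across runs — the property the decoder
exploits). Control regions use amplitude 0, making their series
statistically independent of the labels.

`signal_amplitude` defaults to 0.06 (per-voxel condition response relative
to unit noise SD), chosen so that 200-voxel ROIs decode in the upper-50s /
low-60s accuracy range — the regime reported for executed-action MVPA with
anatomically defined ROIs. A lognormal per-subject amplitude factor
(σ = 0.4) makes subjects differ in decodability; the IFG and mPFC share
their factor by default, inducing a positive across-subject correlation
between their accuracies while other region pairs stay uncorrelated.

Not emulated: spatial voxel geometry and smoothness, physiological noise
spectra, motion artifacts, inter-regional time-series correlations.

## Decoding

Runs are conditioned independently and label-free: linear detrend, then
regression on a discrete-cosine basis with frequencies below 0.01 Hz (the
convention of SPM-style preprocessing; a zero-phase Butterworth alternative
sits behind `method="butter"`), then per-voxel z-scoring. Patterns average
the volumes acquired in [onset+3 s, onset+6 s) — with TR = 3 s and jittered
onsets this selects one or two volumes; interpolation is deliberately
avoided. Bilateral ROIs are decoded per hemisphere and pooled by feature
concatenation.

Fold pairing for the balanced leave-one-pair-out loop is by within-condition
acquisition order (run, then onset) — deterministic and reproducible; a
seeded random pairing is available for sensitivity checks. A decision value
of exactly zero counts as incorrect (conservative, measure-zero). Accuracy
is the fraction of correct held-out predictions over all folds; with exactly
two held-out samples per fold, per-fold averaging and pooling coincide.

On signal-free data the loop shows the small pessimistic bias expected of
leave-pair-out schemes (group means ~0.47–0.50 rather than exactly 0.50):
removing a pair tilts the training set slightly against the held-out
samples. The published control-region values show the same signature
(means of .49–.50 with negative t statistics).

Group inference: one-sample upper-tailed t against 0.5 (the only meaningful
direction for accuracy) with one-sided CIs; two-sided paired t for
left-vs-right; repeated-measures ANOVA with the Greenhouse–Geisser epsilon
always applied to both degrees of freedom (via pingouin); Pearson
correlations with two-sided p-values entering a Benjamini–Hochberg step-up
adjustment.

## Problem sizes used in the test and acceptance runs

Simulation-backed checks run at the sizes that make their statistics
meaningful while staying light: the chance-level and acceptance checks use
the full 23-subject, 2 × 165-volume, 50-trial design (one control region);
monotone-decodability uses 24-voxel, 84-volume single-subject replicates at
three amplitudes; behavioral type-I calibration uses 400 paired-test and 120
ANOVA null replicates; kinematic dataset tests use 2–6 subjects with 1–4
trials per condition, plus one full-design run in the pipeline smoke tests.

## Known limitations

* Exact reproduction of the published per-subject kinematic table is not
  possible from simulation — only the printed effect sizes and test
  structure are calibrated, and truncation to realisable profiles shrinks
  two amplitude-effect means by ~10–15% at default SDs.
* The published "Cohen's d" column for the behavioral comparisons does not
  correspond to any standard paired effect-size definition and is not
  reproduced; d_z is reported instead.
* T_max_grip_apert carries no configurable effect; its social delay emerges
  from movement-time scaling (≈0.6 × the Mov_T effect).
* The 4-D volume + mask adapter for real neuroimaging data is out of scope;
  ROI matrices and events tables in the delimited-text schema are the
  ingestion boundary.
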