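# Methods

This note documents the models behind each pipeline stage, the
parameters that matter (with units and defaults), what the synthetic
generators do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Bout-process model of larval swimming

Larval zebrafish locomotion is modelled as an alternating renewal
process: quiescent intervals (inter-movement intervals, IMI) drawn from
a gamma distribution with shape `imi_shape` and mean `imi_mean`, and
movement bouts with lognormal duration (arithmetic mean `dur_mean`,
log-sd `dur_sigma`) and lognormal within-bout speed (mean `speed_mean`,
sd `speed_sigma`). Right-skewed positive distributions match the
discontinuous, stochastic character of larval swimming; the specific
families are a modelling choice, not an empirical fit. During dark
phases the IMI is divided by `dark_activity_multiplier` (> 1: larvae
swim more in the dark, the normal pattern). Within a bout the fish
moves at its bout speed in a persistent random-walk heading (heading
diffusion 0.3 rad/frame); at rest the observed position carries
Gaussian jitter (`jitter_sd`, default 0.005 mm) emulating centroid
noise. Positions are confined to a well of radius 3.2 mm (a 96-well
plate well) by radial fold-back at the wall.

Two presets bracket the phenotypes:

| parameter | control | Tau regime |
|---|---|---|
| `imi_mean` (s) | 2.0 | 10.0 |
| `dur_mean` (s) | 0.4 | 0.3 |
| `speed_mean` (mm/s) | 8.0 | 6.0 |

The Tau preset reproduces the *directions* of the hypokinetic
phenotype — a several-fold longer interval between movements with
slightly shorter and modestly slower bouts — not calibrated magnitudes;
the underlying study reports these effects only graphically. Drug
effects interpolate between the two presets along a rescue fraction
r ∈ [0, 1] (r = 0 is Tau, r = 1 is control).

Closed forms used as oracles: the expected fraction of time in bouts is
dur/(dur + imi) (renewal reward theorem) and the expected mean scalar
speed is that fraction times the mean bout speed.

**What the generator does not emulate**: wall-following behaviour,
burst/glide substructure within bouts, habituation or circadian drift,
inter-fish variability in bout parameters (each simulated fish has the
preset parameters exactly). Passing recovery tests therefore shows the
estimators are unbiased for the renewal model, not that real tracks
satisfy that model.

A note on confinement: inside a 3.2 mm well a control fish's bouts
(~3 mm of travel) regularly reach the wall, where fold-back shortens
the observed displacement. Parameter-recovery validations are therefore
run in an effectively open arena (`well_radius_mm = 100`) to isolate
estimator behaviour from confinement, which is a property of the
environment rather than of the estimator.

## Bout detection and locomotor metrics

A bout is a maximal run of frame transitions with instantaneous speed
above `activity_threshold` (default 1 mm/s — the assay never defines
"active", so the threshold is configuration with a documented default);
sub-threshold gaps shorter than `min_gap` (0.2 s) are merged and bouts
shorter than `min_duration` (0.08 s) dropped. The IMI is the bout-end to
next-bout-start gap, distinct from bout duration. Invalid (tracking
failure) frames break bouts rather than being interpolated —
conservative and simple. Times are seconds from recording start, frames
0-based, intervals half-open. A track with zero bouts reports IMI and
bout duration as NaN, never zero. The tracking QC gate excludes wells
with strictly more than 5% invalid frames (a boundary well at exactly
5% passes).

The VMR endpoint is the mean instantaneous speed over all frames of the
requested phase; with equal-length half-cycles this equals the
cycle-averaged response. The default protocol is a 60-min light
baseline then 3 × (10 min dark + 10 min light). The plate camera rate
defaults to 25 Hz and the spatial calibration to 1 mm/unit; both are
configuration, as they are hardware properties.

## Optokinetic model and analysis

The simulator integrates eye angle at `gain` × stimulus velocity plus
white velocity noise (`noise_sd`, deg/s). When eccentricity from rest
exceeds `eccentricity_limit` (15°), a resetting saccade of
`saccade_amplitude` at `saccade_peak_velocity` (300 deg/s) fires toward
rest. The default amplitude equals the eccentricity limit, so a reset
returns the eye to rest and the expected saccade frequency in an
uninterrupted block is the closed form g·v/L — the integrator-reset
picture in which saccade frequency is a derived quantity of gain, as in
real optokinetic nystagmus. `saccade_suppressed` models fish that track
without ever resetting. The contralateral eye runs the same integrator
at gain c·g (`interocular_coupling` c).

Analysis: eye velocity by central differences after a 5-frame moving
average; saccades are maximal runs with |velocity| > 50 deg/s (more
than 3× the 15 deg/s stimulus; the threshold must exceed the stimulus
speed or the contract is violated) whose net angle change opposes the
concurrent slow-phase direction, gated at 5° minimum amplitude. Gain is
the median of per-frame signed velocity ratios over non-saccadic frames
(median rather than mean: robust to residual saccade contamination),
pooled over the whole alternating block rather than per 10-s
sub-segment (configurable). Interocular gain is the contralateral gain
divided by the stimulated-eye gain. Ocular range is max − min eye angle
per uninterrupted block. A missing protocol block leaves its metrics
NaN without failing the others.

## O-bend model and analysis

Each dark-flash trial is 1 s of pose at 1000 frames/s (plus a 100-frame
pre-stimulus baseline). With probability `response_prob` a curvature
pulse starts after a truncated-normal latency (mean 15 ms, sd 3 ms):
a quarter-sine rise to `peak_curvature` (120°) over `curvature_rise_ms`
(10 ms) and a half-cosine decay over 3× the rise time, distributed
evenly across the midline segments. The quarter-sine rise is steepest
at onset — appropriate for a ballistic startle bend — which also makes
the threshold-crossing time essentially coincide with pulse onset, so
the analyzer's latency estimator is unbiased to within one frame. The
analytic maximum of |dκ/dt| is P·π/(2·T_rise), used as the oracle for
the peak-angular-velocity estimator.

Analysis: total curvature is the summed signed deviation of
inter-segment angles from the baseline posture (per-segment median over
the 50 pre-stimulus frames — robust to pre-stimulus wobble), reported
as magnitude; it is invariant to whole-body rigid rotation, which
shifts absolute headings but no inter-segment angle. A response is a
crossing of `onset_threshold` (15° total curvature, a documented
default; the original criterion is unstated) within 1 s of the
stimulus. Kinematic endpoints average over responding trials only —
non-responses carry no kinematics but still count in the response rate.

## Screening statistics

Z-factor uses sample SDs (n − 1) throughout, as does the 3-SD hit
threshold. Group-size curves shuffle each arm, partition into disjoint
groups of exactly the requested size (remainder discarded), and compute
Z' on group means; 100 fresh shuffles per size, all from one seeded
generator. Size 1 with a single grouping reduces exactly to the raw
Z-factor.

Rescue normalization is per plate — each plate carries its own
untreated Tau and sibling control groups — so inter-assay drift cancels.
The hit rule is strict inequality at library mean + 3 SD with no
trimming of candidate hits from the library statistics (no trimming is
described for the assay this emulates). The per-compound SE is the SD
of its fish endpoints rescaled to rescue units over √n.

The MTC ladder defaults to {50, 25, 10, 5, 2, 1, 0.5} µM: the staging
protocol starts at 50 µM and descends while intolerant; 2 µM appears
among realized MTCs in practice so the ladder includes it. Compounds
intolerant at the floor are flagged unusable. The plate QC gate fails
inverted windows (sibling mean ≤ Tau mean), windows narrower than
0.3 mm/s (configurable; the original benchmark values are not public),
or control groups reduced below 6 fish by tracking QC.

The screen generator draws per-fish endpoints from a normal
distribution centred on the linear interpolation between the expected
Tau and control mean speeds at the compound's rescue fraction — linear
on the rescue axis, so a planted r is exactly the expected percent
rescue (interpolating bout parameters instead would make the endpoint
nonlinear in r). The per-fish noise SD (0.25 mm/s, ~22% of the
phenotypic window) is sized so that single-fish arms overlap (Z'
negative) while group-of-12 means separate cleanly (Z' ≈ +0.6) and
hits planted at r = 0.6–0.75 are recovered essentially always —
jointly the behaviour the assay this emulates exhibits. Default
planted hits: compounds 17, 64 and 110 at r = 0.75, 0.65, 0.60.

## 3D puncta quantification

Detection: the puncta channel is min–max normalized (affine-invariant),
smoothed with a Gaussian matched to the punctum (σ = radius/2 per axis
in voxels — anisotropic voxels scale the filter), and the global median
is subtracted as the background estimate; together a band-pass at the
punctum scale. The threshold is 0.65 of a robust response peak (99.99th
percentile of positive response — stable against single hot voxels,
unlike the absolute maximum). Components are labelled with
26-connectivity and gated to [2, 100] µm³; components containing
several response maxima (footprint ≈ one punctum diameter) are split
into one detection per maximum, so touching puncta are not undercounted.
This operating point was validated on synthetic ground truth: exact
counts at infinite SNR, ≤ 2% total-count error at SNR 5 (peak
amplitude / read-noise sd), per-cell mean absolute error ≤ 0.4.

Cell segmentation: Gaussian smoothing (1 µm), normalization after
smoothing (so read noise does not stretch the intensity range), global
threshold at 0.5 — the half-height of a plateau-like cytoplasmic label
recovers the true boundary — 3D components, 50 µm³ minimum volume.
Segmented volumes run ~8% below the geometric sphere volume from
boundary-curvature erosion; within the 10% the validation demands.

A punctum is inside a cell iff its centroid voxel carries the cell's
label; a centroid on a background voxel adjacent to a cell counts
outside. The rule is configurable but centroid containment is the
default (the vendor software this stands in for does not disclose its
rule; this module is a principled stand-in validated on synthetic
ground truth, not a re-implementation). One global threshold per
experiment honours the identical-settings constraint that makes group
comparisons unbiased.

The stack generator packs spherical cells (radius 8 µm) on a jittered
grid (guaranteed non-overlap; impossible packings are rejected), places
the stated number of Gaussian puncta (radius 1.5 µm) well inside each
cell with ≥ 2.5 radii mutual separation, adds Poisson-distributed
background puncta at the stated density, and Gaussian read noise at
1/SNR of the unit peak. It does not emulate depth-dependent
attenuation, anisotropic PSFs, autofluorescence texture, or puncta
straddling cell boundaries.

## Problem sizes and determinism

Validation runs use: 1-h sessions at 25 Hz for bout-parameter recovery;
the full 3-min optokinetic protocol at 30 Hz; 40 dark-flash trials ×
100 fish for startle statistics; 100–200 seeded replicate screens of
147 compounds for hit-recovery and null-rate checks; and
48 × 256 × 256-voxel stacks with 20 cells × 10 puncta for image
quantification — sizes at which every stochastic tolerance is set by
the derived standard error, not by convenience. Every simulator is a
pure function of (parameters, seed): identical inputs give
bit-identical outputs, and seeds are recorded in output metadata.

## Known limitations

- The bout, eye, and startle generators are phenomenological; they
  support estimator validation, not biomechanical inference.
- Gain estimation assumes the slow phase tracks in the stimulus
  direction; gains near zero make the interocular ratio unstable
  (reported NaN on a zero denominator).
- The screen generator models a single endpoint (VMR light-phase
  speed); multi-endpoint screening would need a vectorized rescue
  definition.
- Puncta detection assumes roughly isotropic, similar-sized puncta;
  strongly varying punctum sizes would need a multi-scale detector.
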