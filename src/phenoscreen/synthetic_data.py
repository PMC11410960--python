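"""Synthetic data generators with known ground truth.

Every input consumed by the analysis stages can be produced here, so the
whole pipeline is testable without raw video or image data:

* bout-structured larval swimming (alternating renewal process of rest
  and movement epochs) with light/dark modulation, a hypokinetic "Tau"
  regime, and drug effects as fractional interpolation between the Tau
  and control parameter sets;
* optokinetic nystagmograms — slow-phase tracking at a set gain with
  eccentricity-triggered resetting saccades;
* O-bend pose traces around dark-flash stimuli;
* a multi-plate compound screen with planted hits;
* two-channel 3D stacks with puncta inside and outside labelled cell
  volumes.

All simulators are pure functions of their parameters and seed: the same
(spec, seed) yields bit-identical output, and the seed is recorded in the
output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .motor_metrics import CentroidTrack
from .okr_analysis import Nystagmogram
from .obend_analysis import PoseTrace
from .screen_stats import (CompoundRecord, ScreenDataset, DEFAULT_MTC_LADDER,
                           plate_capacity)
from .puncta3d import SynapseStack

__all__ = [
    "BoutParams", "PhenotypeSpec", "CTRL_BOUTS", "TAU_BOUTS",
    "OKRSimParams", "StimulusProgram", "OBendSimParams",
    "ScreenSpec", "StackSpec", "StackGroundTruth",
    "interpolate_params", "expected_fraction_active", "expected_mean_speed",
    "simulate_bout_track", "simulate_nystagmogram", "simulate_obend_trials",
    "simulate_screen", "simulate_synapse_stack",
    "obend_pulse", "obend_pulse_peak_velocity",
]


# --------------------------------------------------------------------------
# bout-structured swimming
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutParams:
    """Generative parameters of the alternating rest/bout renewal process.

    Inter-movement intervals are gamma(imi_shape, imi_mean/imi_shape);
    bout durations and within-bout speeds are lognormal (right-skewed
    positives, matching the discontinuous stochastic character of larval
    swimming).  In dark phases the rest intervals are divided by
    ``dark_activity_multiplier`` (>1 means more active in the dark, the
    normal larval pattern).
    """

    imi_mean: float = 2.0       # s, mean inter-movement interval
    imi_shape: float = 1.5      # gamma shape
    dur_mean: float = 0.4       # s, mean bout duration
    dur_sigma: float = 0.4      # lognormal sigma (dimensionless)
    speed_mean: float = 8.0     # mm/s, mean within-bout speed
    speed_sigma: float = 2.0    # mm/s, SD of within-bout speed
    dark_activity_multiplier: float = 1.5
    jitter_sd: float = 0.005    # mm, per-frame positional noise at rest

    def __post_init__(self) -> None:
        for name in ("imi_mean", "imi_shape", "dur_sigma",
                     "speed_mean", "dark_activity_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dur_mean < 0 or self.speed_sigma < 0 or self.jitter_sd < 0:
            raise ValueError("dur_mean, speed_sigma, jitter_sd must be >= 0")


#: Illustrative healthy-control preset.
CTRL_BOUTS = BoutParams()

#: Illustrative hypokinetic Tau preset: several-fold longer intervals
#: between movements, slightly shorter bouts, modestly slower swimming.
TAU_BOUTS = BoutParams(imi_mean=10.0, dur_mean=0.3, speed_mean=6.0)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Drug effect as linear interpolation between Tau (r=0) and control
    (r=1) bout parameters."""

    ctrl: BoutParams = CTRL_BOUTS
    tau: BoutParams = TAU_BOUTS
    rescue_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ValueError("rescue_fraction must lie in [0, 1]")

    def params(self, r: float | None = None) -> BoutParams:
        return interpolate_params(self.tau, self.ctrl,
                                  self.rescue_fraction if r is None else r)


def interpolate_params(tau: BoutParams, ctrl: BoutParams,
                       r: float) -> BoutParams:
    """Per-field linear interpolation; r=0 gives tau, r=1 gives ctrl."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("rescue fraction must lie in [0, 1]")
    if r == 0.0:
        return tau
    if r == 1.0:
        return ctrl

    def mix(a: float, b: float) -> float:
        return (1.0 - r) * a + r * b

    return BoutParams(
        imi_mean=mix(tau.imi_mean, ctrl.imi_mean),
        imi_shape=mix(tau.imi_shape, ctrl.imi_shape),
        dur_mean=mix(tau.dur_mean, ctrl.dur_mean),
        dur_sigma=mix(tau.dur_sigma, ctrl.dur_sigma),
        speed_mean=mix(tau.speed_mean, ctrl.speed_mean),
        speed_sigma=mix(tau.speed_sigma, ctrl.speed_sigma),
        dark_activity_multiplier=mix(tau.dark_activity_multiplier,
                                     ctrl.dark_activity_multiplier),
        jitter_sd=mix(tau.jitter_sd, ctrl.jitter_sd),
    )


def expected_fraction_active(params: BoutParams, phase: str = "light") -> float:
    """Renewal expectation of the fraction of time spent in bouts."""
    imi = params.imi_mean
    if phase == "dark":
        imi /= params.dark_activity_multiplier
    return params.dur_mean / (params.dur_mean + imi)


def expected_mean_speed(params: BoutParams, phase: str = "light") -> float:
    """Expected mean scalar speed: fraction active times mean bout speed
    (rest frames contribute only jitter-scale displacement)."""
    return expected_fraction_active(params, phase) * params.speed_mean


def simulate_bout_track(params: BoutParams,
                        phase_schedule: list[tuple[float, str]],
                        frame_rate: float = 25.0,
                        seed: int | np.random.Generator = 0,
                        fish_id: str = "sim",
                        well_radius_mm: float = 3.2,
                        mm_per_unit: float = 1.0) -> CentroidTrack:
    """Simulate a centroid track as an alternating renewal process.

    ``phase_schedule`` is a list of (duration s, "light"|"dark")
    segments.  Rest epochs draw a gamma inter-movement interval (scaled
    by 1 / dark multiplier while dark); bout epochs draw a lognormal
    duration and a lognormal within-bout speed, and move the fish in a
    persistent random-walk heading at that speed.  Rest frames get
    Gaussian positional jitter of SD ``jitter_sd``; positions are
    confined to the well radius by reflection.  The plate camera rate
    defaults to 25 Hz.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if not phase_schedule:
        raise ValueError("phase schedule must be non-empty")
    for dur, phase in phase_schedule:
        if phase not in ("light", "dark"):
            raise ValueError(f"unknown phase label {phase!r}")
        if dur <= 0:
            raise ValueError("phase durations must be positive")

    rng = np.random.default_rng(seed)
    total_s = sum(d for d, _ in phase_schedule)
    n_frames = int(round(total_s * frame_rate)) + 1

    # per-frame dark flag
    dark = np.zeros(n_frames, dtype=bool)
    t0 = 0.0
    for dur, phase in phase_schedule:
        if phase == "dark":
            lo = int(round(t0 * frame_rate))
            hi = int(round((t0 + dur) * frame_rate))
            dark[lo:hi] = True
        t0 += dur

    # lognormal(mu, sigma) with a stated arithmetic mean
    def logn_mu(mean: float, sigma: float) -> float:
        return math.log(mean) - 0.5 * sigma * sigma

    # SD -> sigma for lognormal speed with stated mean and SD
    if params.speed_sigma > 0:
        cv2 = (params.speed_sigma / params.speed_mean) ** 2
        sp_sigma = math.sqrt(math.log1p(cv2))
    else:
        sp_sigma = 0.0
    sp_mu = logn_mu(params.speed_mean, sp_sigma)

    active = np.zeros(n_frames, dtype=bool)
    frame_speed = np.zeros(n_frames)        # mm/s while in a bout
    bout_id = np.full(n_frames, -1, dtype=int)

    frame = 0
    n_bouts = 0
    gamma_scale = params.imi_mean / params.imi_shape
    while frame < n_frames:
        # rest epoch
        imi = rng.gamma(params.imi_shape, gamma_scale)
        if dark[min(frame, n_frames - 1)]:
            imi /= params.dark_activity_multiplier
        frame += max(1, int(round(imi * frame_rate)))
        if frame >= n_frames:
            break
        # bout epoch
        if params.dur_mean <= 0:
            continue
        dur = rng.lognormal(logn_mu(params.dur_mean, params.dur_sigma),
                            params.dur_sigma)
        speed = rng.lognormal(sp_mu, sp_sigma) if sp_sigma > 0 else params.speed_mean
        n_bout = max(1, int(round(dur * frame_rate)))
        hi = min(frame + n_bout, n_frames)
        active[frame:hi] = True
        frame_speed[frame:hi] = speed
        bout_id[frame:hi] = n_bouts
        n_bouts += 1
        frame = hi

    # trajectory: persistent random-walk heading during bouts
    headings = rng.uniform(0, 2 * np.pi, size=max(n_bouts, 1))
    turn_sd = 0.3  # rad per frame of heading diffusion within a bout
    turns = rng.normal(0.0, turn_sd, size=n_frames)
    pos = np.zeros((n_frames, 2))
    xy = np.array([0.0, 0.0])
    heading = headings[0] if n_bouts else 0.0
    prev_bout = -1
    step = 1.0 / frame_rate
    for i in range(n_frames):
        if active[i]:
            b = bout_id[i]
            if b != prev_bout:
                heading = headings[b]
                prev_bout = b
            else:
                heading += turns[i]
            xy = xy + frame_speed[i] * step * np.array([np.cos(heading),
                                                        np.sin(heading)])
            r = np.hypot(*xy)
            if r > well_radius_mm:  # reflect at the well wall
                xy *= (2 * well_radius_mm - r) / r
        pos[i] = xy

    jitter = rng.normal(0.0, params.jitter_sd, size=(n_frames, 2))
    jitter[active] = 0.0
    observed = (pos + jitter) / mm_per_unit

    seed_repr = seed if isinstance(seed, int) else "generator"
    return CentroidTrack(
        fish_id=fish_id, frame_rate=frame_rate, mm_per_unit=mm_per_unit,
        positions=observed,
        meta={"seed": seed_repr, "params": params, "n_bouts": n_bouts,
              "active_frames": int(active.sum()),
              "well_radius_mm": well_radius_mm},
    )


# --------------------------------------------------------------------------
# optokinetic nystagmograms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProgram:
    """Grating motion program: (duration s, direction ±1, deg/s) segments
    plus the grating spatial period."""

    segments: tuple[tuple[float, int, float], ...]
    spatial_period: float = 15.0  # deg/cycle
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("stimulus program must be non-empty")
        for dur, direction, speed in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if direction not in (-1, 1):
                raise ValueError("direction must be +1 or -1")

    @property
    def temporal_frequency(self) -> float:
        """Grating cycles per second at the (first-segment) drift speed."""
        return abs(self.segments[0][2]) / self.spatial_period

    @classmethod
    def default(cls, speed: float = 15.0,
                spatial_period: float = 15.0) -> "StimulusProgram":
        """Standard protocol: 60 s alternating direction every 10 s, then
        60 s uninterrupted NT, then 60 s uninterrupted TN, at 15 deg/s on
        a 15 deg/cycle grating (temporal frequency 1 cycle/s)."""
        segs: list[tuple[float, int, float]] = []
        labels: list[str] = []
        for i in range(6):
            segs.append((10.0, 1 if i % 2 == 0 else -1, speed))
            labels.append("alternating")
        segs.append((60.0, 1, speed))
        labels.append("NT")
        segs.append((60.0, -1, speed))
        labels.append("TN")
        return cls(tuple(segs), spatial_period, tuple(labels))

    def per_frame(self, frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
        """Signed velocity (deg/s) and block label per frame."""
        vels: list[np.ndarray] = []
        labs: list[np.ndarray] = []
        labels = self.labels or tuple(f"seg{i}" for i in range(len(self.segments)))
        for (dur, direction, speed), lab in zip(self.segments, labels):
            n = int(round(dur * frame_rate))
            vels.append(np.full(n, direction * speed))
            labs.append(np.full(n, lab, dtype=object))
        return np.concatenate(vels), np.asarray(np.concatenate(labs), dtype=str)


@dataclass(frozen=True)
class OKRSimParams:
    """Slow-phase/saccade generator parameters.

    The eye integrates gain x stimulus velocity plus white velocity
    noise; when eccentricity from rest exceeds ``eccentricity_limit`` a
    resetting saccade of ``saccade_amplitude`` at
    ``saccade_peak_velocity`` fires toward rest (integrator reset), so
    saccade frequency is a derived quantity of gain as in real OKR.  The
    contralateral eye tracks at gain ``interocular_coupling * gain``.
    ``saccade_suppressed`` models saccade-free fish.
    """

    gain: float = 0.8
    saccade_amplitude: float = 15.0       # deg; = eccentricity_limit, so a
                                          # reset returns the eye to rest
    eccentricity_limit: float = 15.0      # deg
    saccade_peak_velocity: float = 300.0  # deg/s
    interocular_coupling: float = 1.0
    noise_sd: float = 1.0                 # deg/s velocity noise
    saccade_suppressed: bool = False

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.eccentricity_limit <= 0:
            raise ValueError("eccentricity_limit must be positive")
        if not 0.0 <= self.interocular_coupling <= 1.0:
            raise ValueError("interocular_coupling must lie in [0, 1]")
        if self.noise_sd < 0 or self.saccade_amplitude < 0:
            raise ValueError("noise_sd and saccade_amplitude must be >= 0")


def simulate_nystagmogram(okr: OKRSimParams,
                          stim: StimulusProgram | None = None,
                          frame_rate: float = 30.0,
                          seed: int | np.random.Generator = 0) -> Nystagmogram:
    """Simulate a two-eye nystagmogram for a stimulus program.

    Both eyes integrate their gain-scaled stimulus velocity with
    independent noise; each eye fires resetting saccades from its own
    eccentricity integrator (conjugate behaviour emerges when the gains
    match).  Eye traces and the stimulus trace share one frame clock at
    30 frames/s by default.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    stim = stim or StimulusProgram.default()
    rng = np.random.default_rng(seed)
    stim_vel, labels = stim.per_frame(frame_rate)
    n = len(stim_vel)
    dt = 1.0 / frame_rate

    def one_eye(gain: float) -> tuple[np.ndarray, int]:
        theta = np.zeros(n)
        angle = 0.0
        n_sacc = 0
        saccade_left = 0.0  # remaining saccade amplitude (signed)
        for i in range(n):
            if saccade_left != 0.0:
                step = math.copysign(
                    min(abs(saccade_left), okr.saccade_peak_velocity * dt),
                    saccade_left)
                angle += step
                saccade_left -= step
            else:
                v = gain * stim_vel[i]
                if okr.noise_sd > 0:
                    v += rng.normal(0.0, okr.noise_sd)
                angle += v * dt
                if (abs(angle) > okr.eccentricity_limit
                        and not okr.saccade_suppressed):
                    saccade_left = -math.copysign(okr.saccade_amplitude, angle)
                    n_sacc += 1
            theta[i] = angle
        return theta, n_sacc

    theta_stim, n_sacc_stim = one_eye(okr.gain)
    theta_contra, n_sacc_contra = one_eye(okr.interocular_coupling * okr.gain)

    seed_repr = seed if isinstance(seed, int) else "generator"
    return Nystagmogram(
        frame_rate=frame_rate,
        theta_stimulated=theta_stim,
        theta_contralateral=theta_contra,
        stim_velocity=stim_vel,
        segment_labels=labels,
        meta={"seed": seed_repr, "params": okr,
              "n_saccades_stimulated": n_sacc_stim,
              "n_saccades_contralateral": n_sacc_contra},
    )


# --------------------------------------------------------------------------
# O-bend trials
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OBendSimParams:
    response_prob: float = 0.9
    latency_mean: float = 15.0      # ms
    latency_sd: float = 3.0         # ms (truncated at 0)
    peak_curvature: float = 120.0   # deg total trunk curvature
    curvature_rise_ms: float = 10.0
    n_segments: int = 8
    baseline_noise_deg: float = 0.2  # per-segment angle noise

    def __post_init__(self) -> None:
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must lie in [0, 1]")
        if self.latency_mean <= 0:
            raise ValueError("latency_mean must be positive")
        if self.peak_curvature < 0:
            raise ValueError("peak_curvature must be >= 0")
        if self.n_segments < 2:
            raise ValueError("need at least 2 midline segments")


def obend_pulse(t_ms: np.ndarray, peak: float, rise_ms: float,
                decay_ms: float | None = None) -> np.ndarray:
    """Curvature pulse: quarter-sine rise to the peak (steepest at onset,
    as in a ballistic bend), half-cosine decay back to baseline (decay
    defaults to 3x the rise time)."""
    decay_ms = 3.0 * rise_ms if decay_ms is None else decay_ms
    out = np.zeros_like(t_ms, dtype=float)
    rising = (t_ms >= 0) & (t_ms < rise_ms)
    out[rising] = peak * np.sin(0.5 * np.pi * t_ms[rising] / rise_ms)
    falling = (t_ms >= rise_ms) & (t_ms < rise_ms + decay_ms)
    out[falling] = peak * 0.5 * (1 + np.cos(np.pi * (t_ms[falling] - rise_ms)
                                            / decay_ms))
    return out


def obend_pulse_peak_velocity(peak: float, rise_ms: float) -> float:
    """Analytic maximum |d curvature/dt| of the quarter-sine rise (at
    pulse onset), in degrees per second."""
    return peak * np.pi / (2.0 * rise_ms / 1000.0)


def simulate_obend_trials(p: OBendSimParams, n_stimuli: int = 40,
                          frame_rate: float = 1000.0,
                          seed: int | np.random.Generator = 0,
                          pre_stimulus_frames: int = 100,
                          ) -> tuple[list[PoseTrace], list[int]]:
    """Simulate dark-flash trials: 1 s of pose per stimulus at 1000
    frames/s, preceded by a short pre-stimulus baseline.

    With probability ``response_prob`` a curvature pulse begins after a
    truncated-normal latency; otherwise the segment angles stay at
    baseline noise.  The pulse is distributed evenly across the midline
    segments so the summed inter-segment deviation equals the planted
    total curvature.  Returns the traces and the stimulus frame indices.
    """
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    rng = np.random.default_rng(seed)
    n_post = int(round(frame_rate))  # 1 s response window
    n_frames = pre_stimulus_frames + n_post
    seed_repr = seed if isinstance(seed, int) else "generator"

    traces: list[PoseTrace] = []
    stim_frames: list[int] = []
    for trial in range(n_stimuli):
        angles = rng.normal(0.0, p.baseline_noise_deg,
                            size=(n_frames, p.n_segments))
        responded = rng.random() < p.response_prob
        latency_ms = float("nan")
        if responded:
            latency_ms = rng.normal(p.latency_mean, p.latency_sd)
            while latency_ms < 0:
                latency_ms = rng.normal(p.latency_mean, p.latency_sd)
            t_ms = (np.arange(n_post) / frame_rate * 1000.0) - latency_ms
            pulse = obend_pulse(t_ms, p.peak_curvature, p.curvature_rise_ms)
            angles[pre_stimulus_frames:] += (pulse / p.n_segments)[:, None]
        traces.append(PoseTrace(
            frame_rate=frame_rate, segment_angles=angles,
            stimulus_frame=pre_stimulus_frames, trial_id=f"trial{trial:03d}",
            meta={"seed": seed_repr, "responded": responded,
                  "latency_ms": latency_ms, "params": p},
        ))
        stim_frames.append(pre_stimulus_frames)
    return traces, stim_frames


# --------------------------------------------------------------------------
# compound screen
# --------------------------------------------------------------------------

TARGET_CLASSES = ("BET", "HDAC", "DNA-MT", "HDM", "HAT", "HMT", "Other")


@dataclass(frozen=True)
class ScreenSpec:
    """Configuration of a synthetic screen run.

    ``planted_hits`` lists (compound index, true rescue fraction); all
    other compounds act at r=0.  ``null_noise_sd`` is the per-fish
    endpoint SD in mm/s, sized so single-fish arms overlap (negative
    single-fish Z') while group-of-12 means separate cleanly, matching
    the behaviour of the real assay.
    """

    n_compounds: int = 147
    group_size: int = 12
    planted_hits: tuple[tuple[int, float], ...] = ((17, 0.75), (64, 0.65),
                                                   (110, 0.60))
    null_noise_sd: float = 0.25  # mm/s, ~22% of the Tau-sibling window
    n_wells: int = 96

    @classmethod
    def with_size(cls, n_compounds: int, **kwargs) -> "ScreenSpec":
        """Spec for a non-default library size, rescaling the default
        planted-hit positions proportionally (3 hits for any n >= 4)."""
        if "planted_hits" not in kwargs:
            default = cls.__dataclass_fields__["planted_hits"].default
            hits = tuple((idx * n_compounds // 147, r) for idx, r in default)
            if len({i for i, _ in hits}) == len(hits) and \
                    all(i < n_compounds for i, _ in hits):
                kwargs["planted_hits"] = hits
            else:
                kwargs["planted_hits"] = ()
        return cls(n_compounds=n_compounds, **kwargs)

    def __post_init__(self) -> None:
        for idx, r in self.planted_hits:
            if not 0 <= idx < self.n_compounds:
                raise ValueError("planted hit index out of range")
            if not 0.0 <= r <= 1.0:
                raise ValueError("planted rescue must lie in [0, 1]")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        # plate must hold its compounds plus the two control groups
        plate_capacity(self.n_wells, self.group_size, 2)


def simulate_screen(spec: ScreenSpec = ScreenSpec(),
                    phenotypes: PhenotypeSpec = PhenotypeSpec(),
                    seed: int | np.random.Generator = 0) -> ScreenDataset:
    """Simulate per-fish VMR light-phase endpoints for a whole screen.

    Each compound's fish are drawn Normal(mu(r), null_noise_sd) where
    mu(r) interpolates the expected light-phase mean speeds of the Tau
    and control phenotypes linearly on the rescue axis, so the planted
    rescue fraction is exactly the expected percent rescue; planted hits
    use their stated rescue fraction, all others r=0.  Each plate
    carries its own untreated Tau (r=0) and sibling (r=1) control
    groups.  Ground-truth hit labels and MTCs are kept in the dataset
    metadata.
    """
    rng = np.random.default_rng(seed)
    per_plate = plate_capacity(spec.n_wells, spec.group_size, 2)
    planted = dict(spec.planted_hits)

    mu_tau = expected_mean_speed(phenotypes.tau)
    mu_ctrl = expected_mean_speed(phenotypes.ctrl)

    def group(r: float) -> np.ndarray:
        mu = (1.0 - r) * mu_tau + r * mu_ctrl
        return rng.normal(mu, spec.null_noise_sd, size=spec.group_size)

    # MTC ground truth, skewed toward the 50 µM ladder top as in practice
    ladder = np.asarray(DEFAULT_MTC_LADDER)
    mtc_probs = np.array([0.45, 0.2, 0.12, 0.1, 0.06, 0.04, 0.03])
    mtcs = rng.choice(ladder, size=spec.n_compounds, p=mtc_probs)

    classes = [TARGET_CLASSES[i % len(TARGET_CLASSES)]
               for i in range(spec.n_compounds)]

    compounds: list[CompoundRecord] = []
    plate_controls: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(spec.n_compounds):
        plate_id = f"plate{i // per_plate:03d}"
        if plate_id not in plate_controls:
            plate_controls[plate_id] = (group(0.0), group(1.0))
        r = planted.get(i, 0.0)
        compounds.append(CompoundRecord(
            compound_id=f"C{i:03d}", target_class=classes[i],
            mtc_uM=float(mtcs[i]), fish_endpoints=group(r),
            plate_id=plate_id))

    seed_repr = seed if isinstance(seed, int) else "generator"
    return ScreenDataset(
        compounds=compounds, plate_controls=plate_controls,
        group_size=spec.group_size,
        meta={"seed": seed_repr, "spec": spec,
              "planted_hits": [f"C{i:03d}" for i in sorted(planted)],
              "mu_tau": mu_tau, "mu_ctrl": mu_ctrl},
    )


# --------------------------------------------------------------------------
# two-channel 3D stacks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    shape: tuple[int, int, int] = (40, 160, 160)     # voxels (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # µm
    n_cells: int = 2
    puncta_inside_per_cell: int = 5
    puncta_outside_density: float = 0.0   # per µm³ of background
    punctum_radius: float = 1.5           # µm
    cell_radius: float = 8.0              # µm
    snr: float = float("inf")             # peak signal over read-noise SD

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.puncta_inside_per_cell < 0:
            raise ValueError("counts must be >= 0")
        if self.puncta_outside_density < 0:
            raise ValueError("outside density must be >= 0")
        if any(self.punctum_radius < v for v in self.voxel_size):
            raise ValueError("punctum_radius must be >= 1 voxel per axis")


@dataclass
class StackGroundTruth:
    cell_labels: np.ndarray                 # int volume, 0 = background
    per_cell_inside: list[int]
    total_inside: int
    n_outside: int
    puncta_coordinates: np.ndarray          # (n, 3) µm, inside then outside
    cell_centers: np.ndarray                # (n_cells, 3) µm


def _add_gaussian_spot(vol: np.ndarray, center_vox: np.ndarray,
                       sigma_vox: np.ndarray, amplitude: float = 1.0) -> None:
    """Add a 3-D Gaussian spot in place (evaluated on a local window)."""
    lo = np.maximum(0, np.floor(center_vox - 4 * sigma_vox).astype(int))
    hi = np.minimum(vol.shape, np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_vox, sigma_vox))
    vol[tuple(slice(l, h) for l, h in zip(lo, hi))] += amplitude * np.exp(-0.5 * d2)


def simulate_synapse_stack(spec: StackSpec = StackSpec(),
                           seed: int | np.random.Generator = 0,
                           ) -> tuple[SynapseStack, StackGroundTruth]:
    """Simulate a two-channel stack with known per-cell puncta counts.

    Cells are spherical blobs on a jittered grid (rejected if they cannot
    be packed without touching); inside puncta are Gaussian spots placed
    well within each cell with a minimum mutual separation; outside
    puncta follow a Poisson count at the stated density in the
    background.  Gaussian read noise is added at SD = 1/snr of the unit
    peak amplitude (snr=inf means noiseless).
    """
    rng = np.random.default_rng(seed)
    shape = spec.shape
    vox = np.asarray(spec.voxel_size)
    extent = np.asarray(shape) * vox  # µm
    r_cell = spec.cell_radius

    # place cell centres on a shuffled grid with jitter: guaranteed non-overlap
    if spec.n_cells > 0:
        pitch = 2.0 * r_cell + 4.0  # µm between grid points
        margin = r_cell + 2.0
        axes = [np.arange(margin, e - margin + 1e-9, pitch) for e in extent]
        if any(len(a) == 0 for a in axes) or \
                np.prod([len(a) for a in axes]) < spec.n_cells:
            raise ValueError("stack too small to pack the requested cells")
        grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
        order = rng.permutation(len(grid))[:spec.n_cells]
        centers = grid[order] + rng.uniform(-1.0, 1.0, size=(spec.n_cells, 3))
    else:
        centers = np.empty((0, 3))

    # cell channel + label volume; intensity is a plateau (smoothed
    # indicator), like a cytoplasmic fluorophore, so a mid-level
    # threshold recovers the true boundary
    from scipy import ndimage as _ndi
    zz, yy, xx = np.meshgrid(*[np.arange(s) * v for s, v in zip(shape, vox)],
                             indexing="ij")
    labels = np.zeros(shape, dtype=np.int32)
    for k, c in enumerate(centers, start=1):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        labels[d2 <= r_cell ** 2] = k
    cell_vol = _ndi.gaussian_filter((labels > 0).astype(float),
                                    sigma=[1.0 / v for v in vox])

    sigma_um = spec.punctum_radius / 2.0
    sigma_vox = np.maximum(sigma_um / vox, 0.5)

    puncta_vol = np.zeros(shape)
    coords: list[np.ndarray] = []
    per_cell_inside: list[int] = []
    min_sep = 2.5 * spec.punctum_radius
    for k, c in enumerate(centers, start=1):
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < spec.puncta_inside_per_cell:
            attempts += 1
            if attempts > 20000:
                raise ValueError("cannot place inside puncta at this density")
            offset = rng.uniform(-1, 1, size=3)
            if np.linalg.norm(offset) > 1:
                continue
            p = c + offset * (r_cell - spec.punctum_radius - 1.0)
            if any(np.linalg.norm(p - q) < min_sep for q in placed):
                continue
            placed.append(p)
        for p in placed:
            _add_gaussian_spot(puncta_vol, p / vox, sigma_vox)
            coords.append(p)
        per_cell_inside.append(len(placed))

    # outside puncta: Poisson count over the background volume
    n_outside = 0
    if spec.puncta_outside_density > 0:
        bg_volume = float((labels == 0).sum()) * float(np.prod(vox))
        n_target = rng.poisson(spec.puncta_outside_density * bg_volume)
        attempts = 0
        while n_outside < n_target and attempts < 100000:
            attempts += 1
            p = rng.uniform(spec.punctum_radius + 1,
                            extent - spec.punctum_radius - 1)
            vox_idx = np.minimum((p / vox).astype(int),
                                 np.asarray(shape) - 1)
            if labels[tuple(vox_idx)] != 0:
                continue
            if centers.size and np.min(
                    np.linalg.norm(centers - p, axis=1)) < r_cell + min_sep:
                continue
            if any(np.linalg.norm(p - q) < min_sep for q in coords):
                continue
            _add_gaussian_spot(puncta_vol, p / vox, sigma_vox)
            coords.append(p)
            n_outside += 1

    if np.isfinite(spec.snr):
        if spec.snr <= 0:
            raise ValueError("snr must be positive")
        noise_sd = 1.0 / spec.snr
        puncta_vol = puncta_vol + rng.normal(0.0, noise_sd, size=shape)
        cell_vol = cell_vol + rng.normal(0.0, noise_sd, size=shape)

    seed_repr = seed if isinstance(seed, int) else "generator"
    stack = SynapseStack(
        puncta_channel=puncta_vol, cell_channel=cell_vol,
        voxel_size=tuple(spec.voxel_size),
        meta={"seed": seed_repr, "spec": spec},
    )
    truth = StackGroundTruth(
        cell_labels=labels,
        per_cell_inside=per_cell_inside,
        total_inside=int(sum(per_cell_inside)),
        n_outside=n_outside,
        puncta_coordinates=(np.asarray(coords) if coords
                            else np.empty((0, 3))),
        cell_centers=centers,
    )
    return stack, truth
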