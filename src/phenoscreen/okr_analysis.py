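"""Optokinetic reflex (OKR) analysis from nystagmograms.

A horizontally drifting grating evokes optokinetic nystagmus in larval
zebrafish: slow tracking eye movements in the stimulus direction,
interrupted by fast resetting saccades in the opposite direction.  From a
nystagmogram (eye angle vs. time for the stimulated and contralateral
eyes, plus the stimulus velocity program) this module computes:

* **reflex gain** — slow-phase eye angular velocity / stimulus angular
  velocity, estimated as the median of per-frame signed velocity ratios
  over non-saccadic frames (robust to residual saccade contamination);
* **ocular range** — max minus min eye angle within each uninterrupted
  stimulus block;
* **saccade frequency** — resetting events per minute over the
  uninterrupted nasotemporal (NT) and temporonasal (TN) blocks;
* **interocular gain** — contralateral / stimulated slow-phase gain;
* **saccade-free classification** — no saccades during either
  uninterrupted nystagmus block.

The standard protocol is 60 s of stimulus alternating direction every
10 s (gain block), then 60 s uninterrupted NT and 60 s uninterrupted TN
(nystagmus blocks), with a 15°/cycle grating at 15°/s, captured at 30
frames/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Nystagmogram",
    "OKRMetrics",
    "OKRConfig",
    "SaccadeEvent",
    "eye_velocity",
    "detect_saccades",
    "slow_phase_gain",
    "compute_okr_metrics",
]


@dataclass
class Nystagmogram:
    """Eye-angle traces and stimulus program on a common frame clock.

    Angles are in degrees (0 = eye long axis parallel to the image
    y-axis); ``stim_velocity`` is the signed stimulus angular velocity in
    degrees/s; ``segment_labels`` tags each frame with its protocol block
    ("alternating", "NT" or "TN").
    """

    frame_rate: float
    theta_stimulated: np.ndarray
    theta_contralateral: np.ndarray
    stim_velocity: np.ndarray
    segment_labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta_stimulated = np.asarray(self.theta_stimulated, dtype=float)
        self.theta_contralateral = np.asarray(self.theta_contralateral, dtype=float)
        self.stim_velocity = np.asarray(self.stim_velocity, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype=str)
        n = len(self.theta_stimulated)
        for arr in (self.theta_contralateral, self.stim_velocity, self.segment_labels):
            if len(arr) != n:
                raise ValueError("all traces must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.theta_stimulated)


@dataclass
class SaccadeEvent:
    """One high-velocity resetting movement."""

    time_s: float          # onset
    amplitude_deg: float   # signed net angle change over the run
    peak_velocity: float   # deg/s, signed at the extremum
    start: int             # frame indices, half-open
    end: int


@dataclass
class OKRMetrics:
    ocular_range_NT: float
    ocular_range_TN: float
    gain: float
    saccade_frequency: float   # per minute over the NT+TN blocks
    interocular_gain: float
    saccade_free: bool
    saccade_events: list[SaccadeEvent]


@dataclass
class OKRConfig:
    saccade_velocity_threshold: float = 50.0  # deg/s, >3x the 15 deg/s stimulus
    min_saccade_amplitude: float = 5.0        # deg
    smooth_frames: int = 5                    # moving-average width for velocity
    saccade_margin_frames: int = 3            # frames excluded around saccades


def eye_velocity(theta: np.ndarray, frame_rate: float,
                 smooth_frames: int = 5) -> np.ndarray:
    """Eye angular velocity (deg/s) by central differences after a
    moving-average smoother."""
    theta = np.asarray(theta, dtype=float)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        theta = np.convolve(theta, kernel, mode="same")
    return np.gradient(theta) * frame_rate


def detect_saccades(nyst: Nystagmogram,
                    velocity_threshold: float = 50.0,
                    min_amplitude: float = 5.0,
                    smooth_frames: int = 5,
                    eye: str = "stimulated") -> list[SaccadeEvent]:
    """Detect resetting saccades in one eye's trace.

    A saccade is a maximal run of frames where the eye's angular speed
    exceeds ``velocity_threshold`` *and* the net angle change over the run
    opposes the concurrent slow-phase (stimulus) direction.  Runs with
    net amplitude below ``min_amplitude`` are discarded.  The threshold
    must exceed the stimulus speed, else slow-phase tracking itself would
    trigger detections.
    """
    stim_speed = float(np.max(np.abs(nyst.stim_velocity)))
    if velocity_threshold <= stim_speed:
        raise ValueError(
            f"velocity_threshold ({velocity_threshold}) must exceed the "
            f"stimulus speed ({stim_speed})")
    theta = (nyst.theta_stimulated if eye == "stimulated"
             else nyst.theta_contralateral)
    vel = eye_velocity(theta, nyst.frame_rate, smooth_frames)
    fast = np.abs(vel) > velocity_threshold

    padded = np.concatenate(([False], fast, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    events: list[SaccadeEvent] = []
    for s, e in zip(edges[::2], edges[1::2]):
        amplitude = theta[min(e, len(theta) - 1)] - theta[s]
        if abs(amplitude) < min_amplitude:
            continue
        # resetting movements oppose the slow-phase (stimulus) direction
        stim_dir = np.sign(np.mean(nyst.stim_velocity[s:e]))
        if stim_dir != 0 and np.sign(amplitude) == stim_dir:
            continue
        seg = vel[s:e]
        peak = float(seg[np.argmax(np.abs(seg))])
        events.append(SaccadeEvent(time_s=s / nyst.frame_rate,
                                   amplitude_deg=float(amplitude),
                                   peak_velocity=peak, start=int(s), end=int(e)))
    return events


def _saccade_mask(n: int, events: list[SaccadeEvent], margin: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for ev in events:
        mask[max(0, ev.start - margin):min(n, ev.end + margin)] = True
    return mask


def slow_phase_gain(nyst: Nystagmogram,
                    saccade_events: list[SaccadeEvent] | None = None,
                    margin_frames: int = 3,
                    smooth_frames: int = 5,
                    eye: str = "stimulated",
                    frames: np.ndarray | None = None) -> float:
    """Slow-phase reflex gain: median signed ratio of eye to stimulus
    angular velocity over non-saccadic frames.

    ``frames`` optionally restricts the estimate to a boolean frame
    selection (e.g. a protocol block).  Returns nan if no usable frames
    remain.
    """
    theta = (nyst.theta_stimulated if eye == "stimulated"
             else nyst.theta_contralateral)
    vel = eye_velocity(theta, nyst.frame_rate, smooth_frames)
    use = nyst.stim_velocity != 0
    if frames is not None:
        use &= frames
    if saccade_events:
        use &= ~_saccade_mask(nyst.n_frames, saccade_events, margin_frames)
    # trim trace edges where central differences/smoothing are one-sided
    k = max(smooth_frames, 2)
    use[:k] = False
    use[-k:] = False
    if not use.any():
        return float("nan")
    return float(np.median(vel[use] / nyst.stim_velocity[use]))


def compute_okr_metrics(nyst: Nystagmogram,
                        cfg: OKRConfig | None = None) -> OKRMetrics:
    """Compute the full OKR endpoint set from one nystagmogram.

    Gain (and interocular gain) come from the alternating block; ocular
    range, saccade frequency and the saccade-free classification from the
    two uninterrupted blocks.  A missing block leaves its metrics nan
    without failing the others.
    """
    cfg = cfg or OKRConfig()
    labels = nyst.segment_labels

    events_stim = detect_saccades(nyst, cfg.saccade_velocity_threshold,
                                  cfg.min_saccade_amplitude, cfg.smooth_frames,
                                  eye="stimulated")
    events_contra = detect_saccades(nyst, cfg.saccade_velocity_threshold,
                                    cfg.min_saccade_amplitude, cfg.smooth_frames,
                                    eye="contralateral")

    alt = labels == "alternating"
    if alt.any():
        gain = slow_phase_gain(nyst, events_stim, cfg.saccade_margin_frames,
                               cfg.smooth_frames, "stimulated", alt)
        gain_contra = slow_phase_gain(nyst, events_contra,
                                      cfg.saccade_margin_frames,
                                      cfg.smooth_frames, "contralateral", alt)
        interocular = gain_contra / gain if gain and np.isfinite(gain) else float("nan")
    else:
        gain = interocular = float("nan")

    ranges = {}
    for block in ("NT", "TN"):
        sel = labels == block
        if sel.any():
            theta = nyst.theta_stimulated[sel]
            ranges[block] = float(theta.max() - theta.min())
        else:
            ranges[block] = float("nan")

    nystagmus = (labels == "NT") | (labels == "TN")
    if nystagmus.any():
        block_events = [ev for ev in events_stim if nystagmus[ev.start]]
        minutes = nystagmus.sum() / nyst.frame_rate / 60.0
        saccade_frequency = len(block_events) / minutes
        saccade_free = len(block_events) == 0
    else:
        block_events = []
        saccade_frequency = float("nan")
        saccade_free = True

    return OKRMetrics(
        ocular_range_NT=ranges["NT"],
        ocular_range_TN=ranges["TN"],
        gain=gain,
        saccade_frequency=saccade_frequency,
        interocular_gain=interocular,
        saccade_free=saccade_free,
        saccade_events=block_events,
    )
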