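"""Locomotor metrics for larval zebrafish centroid tracks.

Larval zebrafish swim in discrete, stochastic bouts separated by quiescent
intervals.  This module turns a per-frame centroid track into the standard
plate-assay endpoints: mean scalar speed, percent time active, mean
inter-movement interval (IMI), mean movement (bout) duration, active
swimming speed, a distance-weighted speed histogram, and the visual motor
response (VMR) phase endpoints obtained under alternating ambient
light/dark illumination.

Conventions: time is seconds from recording start, frames are 0-based,
intervals are half-open ``[start, end)``.  Frame transitions touching a
frame with failed tracking are flagged invalid and never counted as
movement; invalid frames break bouts rather than being interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CentroidTrack",
    "MotorMetrics",
    "MotorConfig",
    "PhaseSchedule",
    "SpeedHistogram",
    "displacement_series",
    "detect_bouts",
    "compute_motor_metrics",
    "vmr_phase_endpoint",
    "qc_tracking",
    "speed_histogram",
]

Phase = Literal["light", "dark"]


@dataclass
class CentroidTrack:
    """Per-fish centroid time series from automated plate tracking.

    Parameters
    ----------
    fish_id : str
        Well/fish identifier.
    frame_rate : float
        Acquisition rate in Hz.
    mm_per_unit : float
        Spatial calibration: millimetres per position unit.
    positions : (n_frames, 2) array
        Centroid x, y per frame, in raw position units.
    valid_mask : (n_frames,) bool array
        True where the tracker reported a valid centroid.
    meta : dict
        Free-form provenance (e.g. simulation seed and parameters).
    """

    fish_id: str
    frame_rate: float
    mm_per_unit: float
    positions: np.ndarray
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_frames, 2) array")
        if self.n_frames < 2:
            raise ValueError("a track needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.mm_per_unit <= 0:
            raise ValueError("mm_per_unit must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.n_frames, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.n_frames,):
                raise ValueError("valid_mask length must match positions")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        """Session duration covered by the frame transitions, in seconds."""
        return (self.n_frames - 1) / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class MotorMetrics:
    """Endpoint summary for one fish.

    Undefined quantities (e.g. IMI of a track with fewer than two bouts)
    are reported as ``nan`` rather than zero.
    """

    fish_id: str
    mean_speed: float          # mm/s over all valid frame transitions
    pct_time_active: float     # % of valid transitions inside bouts
    imi_mean: float            # s, mean bout-end -> next-bout-start gap
    bout_duration_mean: float  # s
    active_speed: float        # mm/s, mean instantaneous speed in bouts
    total_distance: float      # mm over valid transitions
    n_bouts: int


@dataclass
class MotorConfig:
    """Bout-detection configuration.

    The activity threshold defines "active": instantaneous speed above
    ``activity_threshold`` mm/s.  Sub-threshold gaps shorter than
    ``min_gap`` seconds are merged into the surrounding bout; bouts
    shorter than ``min_duration`` seconds are discarded.
    """

    activity_threshold: float = 1.0   # mm/s
    min_gap: float = 0.2              # s
    min_duration: float = 0.08        # s


@dataclass
class PhaseSchedule:
    """Ordered, contiguous light/dark segments labelling a recording.

    ``segments`` is a list of ``(start_s, end_s, phase)`` with phase in
    {"light", "dark"}.
    """

    segments: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, phase in self.segments:
            if end <= start:
                raise ValueError("segment end must exceed start")
            if phase not in ("light", "dark"):
                raise ValueError(f"unknown phase label {phase!r}")
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ValueError("segments must be contiguous")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.segments[-1][1]

    def phases(self) -> set[str]:
        return {seg[2] for seg in self.segments}

    def labels_for(self, times: np.ndarray) -> np.ndarray:
        """Phase label per time point; '' outside the schedule."""
        out = np.full(len(times), "", dtype=object)
        for start, end, phase in self.segments:
            out[(times >= start) & (times < end)] = phase
        return np.asarray(out, dtype=str)

    @classmethod
    def vmr_default(cls, baseline_min: float = 60.0,
                    n_cycles: int = 3, half_cycle_min: float = 10.0,
                    baseline_phase: str = "light") -> "PhaseSchedule":
        """Standard VMR protocol: a baseline recording in constant light
        followed by ``n_cycles`` of (dark + light) half-cycles of
        ``half_cycle_min`` minutes each."""
        segs: list[tuple[float, float, str]] = []
        t = 0.0
        if baseline_min > 0:
            segs.append((0.0, baseline_min * 60.0, baseline_phase))
            t = baseline_min * 60.0
        half = half_cycle_min * 60.0
        for _ in range(n_cycles):
            segs.append((t, t + half, "dark"))
            segs.append((t + half, t + 2 * half, "light"))
            t += 2 * half
        return cls(segs)


@dataclass
class SpeedHistogram:
    """Total distance travelled per instantaneous-speed bin."""

    bin_edges: np.ndarray       # mm/s, len = n_bins + 1
    distance_per_bin: np.ndarray  # mm, len = n_bins


def displacement_series(track: CentroidTrack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame-transition displacement and instantaneous speed.

    Returns ``(displacement_mm, speed_mm_s, valid)`` of length
    ``n_frames - 1``.  A transition is valid only if both flanking frames
    have valid tracking; invalid transitions carry ``nan``.
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    deltas = np.diff(track.positions, axis=0) * track.mm_per_unit
    disp = np.hypot(deltas[:, 0], deltas[:, 1])
    valid = track.valid_mask[:-1] & track.valid_mask[1:]
    disp = np.where(valid, disp, np.nan)
    speed = disp * track.frame_rate
    return disp, speed, valid


def detect_bouts(speed: np.ndarray, frame_rate: float,
                 activity_threshold: float = 1.0,
                 min_gap: float = 0.2,
                 min_duration: float = 0.08) -> list[tuple[int, int]]:
    """Detect swim bouts in an instantaneous-speed series.

    A bout is a maximal run of transitions with ``speed > threshold``
    (NaN, i.e. invalid, frames are never active).  Runs separated by a
    sub-threshold gap shorter than ``min_gap`` seconds are merged; merged
    runs shorter than ``min_duration`` seconds are dropped.  Returns
    half-open ``[start, end)`` transition-index intervals.
    """
    if activity_threshold <= 0:
        raise ValueError("activity_threshold must be positive")
    speed = np.asarray(speed, dtype=float)
    active = np.zeros(len(speed), dtype=bool)
    finite = np.isfinite(speed)
    active[finite] = speed[finite] > activity_threshold

    # maximal runs of active transitions
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    runs = list(zip(starts, ends))
    if not runs:
        return []

    # merge runs separated by short fully-valid gaps
    min_gap_frames = min_gap * frame_rate
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        gap_lo, gap_hi = merged[-1][1], s
        gap_valid = bool(np.all(finite[gap_lo:gap_hi]))
        if (gap_hi - gap_lo) < min_gap_frames and gap_valid:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_dur_frames = min_duration * frame_rate
    return [(s, e) for s, e in merged if (e - s) >= min_dur_frames]


def compute_motor_metrics(track: CentroidTrack,
                          cfg: MotorConfig | None = None) -> MotorMetrics:
    """Compute the standard locomotor endpoint set for one track.

    The decomposition ``mean_speed = f_active * active_speed +
    (1 - f_active) * inactive_speed`` holds exactly over valid
    transitions.  With zero or one bout the IMI is undefined (nan); with
    zero bouts bout duration and active speed are also nan.
    """
    cfg = cfg or MotorConfig()
    disp, speed, valid = displacement_series(track)
    bouts = detect_bouts(speed, track.frame_rate, cfg.activity_threshold,
                         cfg.min_gap, cfg.min_duration)

    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("track has no valid frame transitions")
    total_distance = float(np.nansum(disp))
    mean_speed = float(np.nanmean(speed))

    in_bout = np.zeros(len(speed), dtype=bool)
    for s, e in bouts:
        in_bout[s:e] = True
    n_active = int((in_bout & valid).sum())
    pct_time_active = 100.0 * n_active / n_valid

    if bouts:
        durations = [(e - s) / track.frame_rate for s, e in bouts]
        bout_duration_mean = float(np.mean(durations))
        active_speed = float(np.nanmean(speed[in_bout]))
    else:
        bout_duration_mean = float("nan")
        active_speed = float("nan")

    if len(bouts) >= 2:
        gaps = [(bouts[i + 1][0] - bouts[i][1]) / track.frame_rate
                for i in range(len(bouts) - 1)]
        imi_mean = float(np.mean(gaps))
    else:
        imi_mean = float("nan")

    return MotorMetrics(
        fish_id=track.fish_id,
        mean_speed=mean_speed,
        pct_time_active=pct_time_active,
        imi_mean=imi_mean,
        bout_duration_mean=bout_duration_mean,
        active_speed=active_speed,
        total_distance=total_distance,
        n_bouts=len(bouts),
    )


def qc_tracking(track: CentroidTrack, max_error_frac: float = 0.05) -> bool:
    """Tracking-quality gate: fail iff the fraction of invalid frames is
    strictly greater than ``max_error_frac`` (default 5%).  Failed wells
    are excluded from all group statistics."""
    n_invalid = int(np.count_nonzero(~track.valid_mask))
    return n_invalid <= max_error_frac * track.n_frames


def vmr_phase_endpoint(tracks: Sequence[CentroidTrack],
                       schedule: PhaseSchedule,
                       phase: str) -> np.ndarray:
    """Per-fish mean speed during all segments of the requested phase.

    Because light and dark half-cycles have equal length this equals the
    cycle-averaged phase response.  Raises if the phase does not occur in
    the schedule.
    """
    if phase not in schedule.phases():
        raise ValueError(f"phase {phase!r} absent from schedule")
    out = np.empty(len(tracks))
    for i, track in enumerate(tracks):
        _, speed, _ = displacement_series(track)
        # transition i spans frames [i, i+1); label it by its start time
        t = np.arange(len(speed)) / track.frame_rate
        labels = schedule.labels_for(t)
        sel = labels == phase
        if not sel.any():
            raise ValueError(
                f"track {track.fish_id} has no frames in phase {phase!r}")
        out[i] = float(np.nanmean(speed[sel]))
    return out


def binned_speed_trace(track: CentroidTrack, bin_s: float = 120.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean speed per time bin (default 2 min), for VMR trace plots.

    Returns (bin_centre_s, mean_speed_mm_s).
    """
    _, speed, _ = displacement_series(track)
    t = np.arange(len(speed)) / track.frame_rate
    n_bins = int(np.ceil((len(speed) / track.frame_rate) / bin_s))
    centres = (np.arange(n_bins) + 0.5) * bin_s
    means = np.full(n_bins, np.nan)
    idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
    for b in range(n_bins):
        vals = speed[idx == b]
        if np.isfinite(vals).any():
            means[b] = np.nanmean(vals)
    return centres, means


def speed_histogram(track: CentroidTrack, bin_edges: np.ndarray) -> SpeedHistogram:
    """Distance-weighted instantaneous-speed histogram.

    Each frame transition's displacement accrues to the bin containing its
    instantaneous speed, so the histogram sums to the track's total
    distance (speeds outside the edges accrue to the nearest end bin).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be a monotone 1-D array")
    disp, speed, valid = displacement_series(track)
    n_bins = len(bin_edges) - 1
    idx = np.clip(np.searchsorted(bin_edges, speed[valid], side="right") - 1,
                  0, n_bins - 1)
    dist = np.zeros(n_bins)
    np.add.at(dist, idx, disp[valid])
    return SpeedHistogram(bin_edges=bin_edges, distance_per_bin=dist)
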