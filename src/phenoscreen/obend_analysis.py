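"""O-bend startle kinematics from high-speed midline pose traces.

An abrupt light-to-dark transition (dark flash) evokes a large-curvature
"O-bend" turning manoeuvre in larval zebrafish.  Trials are recorded for
1 s at 1000 frames/s; the input is a per-frame table of midline
inter-segment angles.  Endpoints per fish:

* **response rate** — proportion of stimuli followed by motion within the
  response window (1 s);
* **response latency** — stimulus to movement-onset interval (ms);
* **maximum trunk curvature** — peak of the total-curvature trace (deg);
* **peak truncal angular velocity** — maximum |d(curvature)/dt| (deg/s).

Kinematic endpoints are averaged over responding trials only: a trial
without a response contributes to the response rate but carries no
kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PoseTrace",
    "OBendMetrics",
    "OBendConfig",
    "trunk_curvature",
    "detect_response",
    "compute_obend_metrics",
]


@dataclass
class PoseTrace:
    """Midline pose for one fish around one dark-flash stimulus.

    ``segment_angles`` is an (n_frames, n_segments) array of inter-segment
    angles in degrees; ``stimulus_frame`` indexes the light->dark
    transition within the trace.
    """

    frame_rate: float
    segment_angles: np.ndarray
    stimulus_frame: int
    trial_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segment_angles = np.asarray(self.segment_angles, dtype=float)
        if self.segment_angles.ndim != 2 or self.segment_angles.shape[1] < 2:
            raise ValueError("segment_angles must be (n_frames, >=2 segments)")
        if not 0 <= self.stimulus_frame < self.segment_angles.shape[0]:
            raise ValueError("stimulus_frame outside trace")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.segment_angles.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segment_angles.shape[1]


@dataclass
class OBendMetrics:
    response_rate: float          # proportion of trials with a response
    latency_mean: float           # ms, over responding trials
    max_curvature: float          # deg
    peak_angular_velocity: float  # deg/s
    n_trials: int
    n_responses: int


@dataclass
class OBendConfig:
    onset_threshold: float = 15.0   # deg total curvature marking motion onset
    window_s: float = 1.0           # response window after the stimulus
    baseline_frames: int = 50       # pre-stimulus frames defining straight posture


def trunk_curvature(pose: PoseTrace, baseline_frames: int = 50) -> np.ndarray:
    """Total trunk curvature per frame (degrees, magnitude).

    Curvature is the sum over the midline of signed inter-segment angle
    deviations from the straight-body baseline; the baseline is the
    per-segment median over up to ``baseline_frames`` pre-stimulus frames
    (frame 0 if the stimulus is at the first frame).  The summed signed
    deviation is invariant to whole-body rigid rotation, which shifts all
    absolute headings but no inter-segment angle.
    """
    n_pre = max(1, min(baseline_frames, pose.stimulus_frame))
    baseline = np.median(pose.segment_angles[:n_pre], axis=0)
    signed = (pose.segment_angles - baseline).sum(axis=1)
    return np.abs(signed)


def detect_response(curvature: np.ndarray, stimulus_frame: int,
                    frame_rate: float, window_s: float = 1.0,
                    onset_threshold: float = 15.0) -> tuple[bool, float]:
    """Did curvature cross the onset threshold within the window?

    Returns ``(responded, latency_ms)``; latency is nan for
    non-responses.  Latency is the first crossing frame minus the
    stimulus frame, converted to milliseconds.
    """
    end = stimulus_frame + int(round(window_s * frame_rate))
    window = np.asarray(curvature, dtype=float)[stimulus_frame:min(end, len(curvature))]
    above = np.flatnonzero(window > onset_threshold)
    if len(above) == 0:
        return False, float("nan")
    return True, float(above[0]) / frame_rate * 1000.0


def compute_obend_metrics(traces: Sequence[PoseTrace],
                          cfg: OBendConfig | None = None) -> OBendMetrics:
    """Per-fish O-bend endpoints averaged over a fish's stimulus trials.

    Peak angular velocity is the maximum |d(curvature)/dt| by central
    differences within the response window of each responding trial.
    With zero responding trials the kinematic fields are nan and the
    response rate is 0.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trial")
    cfg = cfg or OBendConfig()

    latencies, peaks, velocities = [], [], []
    n_resp = 0
    for pose in traces:
        curv = trunk_curvature(pose, cfg.baseline_frames)
        responded, latency = detect_response(curv, pose.stimulus_frame,
                                             pose.frame_rate, cfg.window_s,
                                             cfg.onset_threshold)
        if not responded:
            continue
        n_resp += 1
        latencies.append(latency)
        end = pose.stimulus_frame + int(round(cfg.window_s * pose.frame_rate))
        seg = curv[pose.stimulus_frame:min(end, len(curv))]
        peaks.append(float(seg.max()))
        dcurv = np.gradient(seg) * pose.frame_rate
        velocities.append(float(np.max(np.abs(dcurv))))

    return OBendMetrics(
        response_rate=n_resp / len(traces),
        latency_mean=float(np.mean(latencies)) if latencies else float("nan"),
        max_curvature=float(np.mean(peaks)) if peaks else float("nan"),
        peak_angular_velocity=float(np.mean(velocities)) if velocities else float("nan"),
        n_trials=len(traces),
        n_responses=n_resp,
    )
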