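"""Readers and writers for the pipeline's table and image schemas.

All tables are tidy one-row-per-observation CSVs; times are seconds,
angles degrees, lengths mm (tracks) or µm (stacks).  Stacks travel as
multi-page TIFF with the voxel size in the image metadata; ground truth
and run provenance as JSON sidecars.  Write-then-read of every schema
reproduces values exactly within the declared text float format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .motor_metrics import CentroidTrack, MotorMetrics, PhaseSchedule
from .okr_analysis import Nystagmogram
from .obend_analysis import PoseTrace
from .screen_stats import CompoundRecord, ScreenDataset, ScreenResult
from .puncta3d import SynapseStack

FLOAT_FMT = "%.9g"

__all__ = [
    "write_track_csv", "read_track_csv",
    "write_nystagmogram_csv", "read_nystagmogram_csv",
    "write_pose_csv", "read_pose_csv",
    "write_schedule_yaml", "read_schedule_yaml",
    "write_screen_csvs", "read_screen_csvs",
    "write_screen_result", "write_metrics_csv",
    "write_stack_tiff", "read_stack_tiff",
    "write_provenance",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


# ---- centroid tracks ------------------------------------------------------

def write_track_csv(track: CentroidTrack, path: str | Path) -> None:
    """Schema: fish_id, frame, x, y, valid (0/1); frame_rate and
    mm_per_unit recorded in a header comment."""
    path = Path(path)
    df = pd.DataFrame({
        "fish_id": track.fish_id,
        "frame": np.arange(track.n_frames),
        "x": track.positions[:, 0],
        "y": track.positions[:, 1],
        "valid": track.valid_mask.astype(int),
    })
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={track.frame_rate!r} "
                 f"mm_per_unit={track.mm_per_unit!r}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_track_csv(path: str | Path) -> CentroidTrack:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh)
    _require_columns(df, ["fish_id", "frame", "x", "y", "valid"], path)
    return CentroidTrack(
        fish_id=str(df["fish_id"].iloc[0]),
        frame_rate=float(meta["frame_rate_hz"]),
        mm_per_unit=float(meta["mm_per_unit"]),
        positions=df[["x", "y"]].to_numpy(),
        valid_mask=df["valid"].to_numpy().astype(bool),
    )


# ---- nystagmograms --------------------------------------------------------

def write_nystagmogram_csv(nyst: Nystagmogram, path: str | Path) -> None:
    """Schema: t_s, theta_stim_eye_deg, theta_contra_eye_deg,
    stim_vel_deg_s, block_label."""
    path = Path(path)
    t = np.arange(nyst.n_frames) / nyst.frame_rate
    df = pd.DataFrame({
        "t_s": t,
        "theta_stim_eye_deg": nyst.theta_stimulated,
        "theta_contra_eye_deg": nyst.theta_contralateral,
        "stim_vel_deg_s": nyst.stim_velocity,
        "block_label": nyst.segment_labels,
    })
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={nyst.frame_rate!r}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_nystagmogram_csv(path: str | Path) -> Nystagmogram:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh)
    _require_columns(df, ["t_s", "theta_stim_eye_deg", "theta_contra_eye_deg",
                          "stim_vel_deg_s", "block_label"], path)
    return Nystagmogram(
        frame_rate=float(meta["frame_rate_hz"]),
        theta_stimulated=df["theta_stim_eye_deg"].to_numpy(),
        theta_contralateral=df["theta_contra_eye_deg"].to_numpy(),
        stim_velocity=df["stim_vel_deg_s"].to_numpy(),
        segment_labels=df["block_label"].to_numpy(),
    )


# ---- pose traces ----------------------------------------------------------

def write_pose_csv(traces: Sequence[PoseTrace], path: str | Path) -> None:
    """Schema: trial_id, frame, seg1_deg ... segN_deg; the frame rate and
    per-trial stimulus frames go in the header comment."""
    path = Path(path)
    frames = []
    stim = {}
    for trace in traces:
        stim[trace.trial_id] = trace.stimulus_frame
        n_seg = trace.n_segments
        df = pd.DataFrame(trace.segment_angles,
                          columns=[f"seg{i + 1}_deg" for i in range(n_seg)])
        df.insert(0, "frame", np.arange(trace.n_frames))
        df.insert(0, "trial_id", trace.trial_id)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={traces[0].frame_rate!r} "
                 f"stimulus_frames={json.dumps(stim, separators=(',', ':'))}\n")
        combined.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_pose_csv(path: str | Path) -> list[PoseTrace]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=", 1) for item in header[1:].split(maxsplit=1))
        df = pd.read_csv(fh)
    _require_columns(df, ["trial_id", "frame"], path)
    frame_rate = float(meta["frame_rate_hz"])
    stim = json.loads(meta["stimulus_frames"])
    seg_cols = [c for c in df.columns if c.startswith("seg")]
    traces = []
    for trial_id, group in df.groupby("trial_id", sort=False):
        traces.append(PoseTrace(
            frame_rate=frame_rate,
            segment_angles=group[seg_cols].to_numpy(),
            stimulus_frame=int(stim[str(trial_id)]),
            trial_id=str(trial_id),
        ))
    return traces


# ---- phase schedules ------------------------------------------------------

def write_schedule_yaml(schedule: PhaseSchedule, path: str | Path) -> None:
    data = [{"start_s": float(s), "end_s": float(e), "phase": p}
            for s, e, p in schedule.segments]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_schedule_yaml(path: str | Path) -> PhaseSchedule:
    data = yaml.safe_load(Path(path).read_text())
    return PhaseSchedule([(seg["start_s"], seg["end_s"], seg["phase"])
                          for seg in data])


# ---- screen data ----------------------------------------------------------

def write_screen_csvs(screen: ScreenDataset, compounds_path: str | Path,
                      endpoints_path: str | Path) -> None:
    """compounds CSV: compound_id, target_class, mtc_uM, plate_id;
    endpoints CSV: plate_id, group_id, fish_id, endpoint_mm_s."""
    comp_df = pd.DataFrame([{
        "compound_id": c.compound_id, "target_class": c.target_class,
        "mtc_uM": c.mtc_uM, "plate_id": c.plate_id,
    } for c in screen.compounds])
    comp_df.to_csv(compounds_path, index=False, float_format=FLOAT_FMT)

    rows = []
    for c in screen.compounds:
        for j, v in enumerate(c.fish_endpoints):
            rows.append((c.plate_id, c.compound_id, f"fish{j:02d}", v))
    for plate_id, (tau, sib) in screen.plate_controls.items():
        for j, v in enumerate(tau):
            rows.append((plate_id, "TAU_CTRL", f"fish{j:02d}", v))
        for j, v in enumerate(sib):
            rows.append((plate_id, "SIB_CTRL", f"fish{j:02d}", v))
    ep_df = pd.DataFrame(rows, columns=["plate_id", "group_id", "fish_id",
                                        "endpoint_mm_s"])
    ep_df.to_csv(endpoints_path, index=False, float_format=FLOAT_FMT)


def read_screen_csvs(compounds_path: str | Path,
                     endpoints_path: str | Path,
                     group_size: int = 12) -> ScreenDataset:
    comp_df = pd.read_csv(compounds_path)
    _require_columns(comp_df, ["compound_id", "target_class", "mtc_uM",
                               "plate_id"], compounds_path)
    ep_df = pd.read_csv(endpoints_path)
    _require_columns(ep_df, ["plate_id", "group_id", "fish_id",
                             "endpoint_mm_s"], endpoints_path)
    by_group = {(p, g): grp["endpoint_mm_s"].to_numpy()
                for (p, g), grp in ep_df.groupby(["plate_id", "group_id"])}
    controls: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for plate_id in ep_df["plate_id"].unique():
        tau = by_group.get((plate_id, "TAU_CTRL"))
        sib = by_group.get((plate_id, "SIB_CTRL"))
        if tau is None or sib is None:
            raise ValueError(f"plate {plate_id} lacks a control group")
        controls[plate_id] = (tau, sib)
    compounds = [CompoundRecord(
        compound_id=row.compound_id, target_class=row.target_class,
        mtc_uM=float(row.mtc_uM), plate_id=row.plate_id,
        fish_endpoints=by_group[(row.plate_id, row.compound_id)],
    ) for row in comp_df.itertuples()]
    return ScreenDataset(compounds=compounds, plate_controls=controls,
                         group_size=group_size)


def write_screen_result(result: ScreenResult, csv_path: str | Path,
                        json_path: str | Path) -> None:
    df = pd.DataFrame({
        "compound_id": result.compound_ids,
        "target_class": result.target_classes,
        "rescue_percent": result.rescue_percent,
        "rescue_se": result.rescue_se,
        "is_hit": [cid in result.hits for cid in result.compound_ids],
    })
    df.to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    summary = {
        "library_mean": result.library_mean,
        "library_sd": result.library_sd,
        "hit_threshold": result.hit_threshold,
        "hits": result.hits,
        "n_compounds": len(result.compound_ids),
    }
    Path(json_path).write_text(json.dumps(summary, indent=2))


def write_metrics_csv(metrics: Sequence[MotorMetrics], path: str | Path) -> None:
    """One tidy row per fish."""
    df = pd.DataFrame([vars(m) for m in metrics])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---- image stacks ---------------------------------------------------------

def write_stack_tiff(stack: SynapseStack, path: str | Path) -> None:
    """Two-channel multi-page TIFF (ImageJ hyperstack, axes ZCYX) with
    voxel size in the metadata."""
    channels = [stack.puncta_channel]
    if stack.cell_channel is not None:
        channels.append(stack.cell_channel)
    data = np.stack(channels, axis=1).astype(np.float32)  # (Z, C, Y, X)
    z, y, x = stack.voxel_size
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZCYX"},
    )


def read_stack_tiff(path: str | Path,
                    voxel_size: tuple[float, float, float] | None = None,
                    ) -> SynapseStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if voxel_size is None:
            ij = tif.imagej_metadata or {}
            z = float(ij.get("spacing", 1.0))
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            x = xres.value[1] / xres.value[0] if xres else 1.0
            y = yres.value[1] / yres.value[0] if yres else 1.0
            voxel_size = (z, y, x)
    if data.ndim == 3:
        return SynapseStack(puncta_channel=data, voxel_size=voxel_size)
    return SynapseStack(puncta_channel=data[:, 0], cell_channel=data[:, 1],
                        voxel_size=voxel_size)


# ---- provenance -----------------------------------------------------------

def write_provenance(path: str | Path, stage: str, seed: int | None,
                     config: dict) -> None:
    """Record what produced an output directory: stage, seed, config,
    and package version."""
    from . import __version__
    record = {"stage": stage, "seed": seed, "config": config,
              "package_version": __version__}
    Path(path).write_text(json.dumps(record, indent=2, default=str))
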