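"""Plate-based phenotypic screening statistics.

The screen tests each compound, at its maximum tolerated concentration
(MTC), in a group of Tau-model zebrafish and scores rescue of the visual
motor response (VMR) light-phase hypokinesia.  Every plate carries its own
untreated disease-model (Tau) and healthy sibling control groups; each
compound group's mean endpoint is normalized linearly to the within-plate
phenotypic window:

    rescue % = 100 * (x - mean_Tau) / (mean_Sib - mean_Tau)

so the Tau control mean maps to 0% and the sibling control mean to 100%.
Hits are compounds whose rescue strictly exceeds the library mean + 3
sample SDs.  Assay quality is summarized by the Z-factor

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|

computed either on single-fish endpoints or on means of random disjoint
groups of fish, which shrinks the SDs roughly as 1/sqrt(group size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CompoundRecord",
    "ScreenDataset",
    "ScreenResult",
    "ZFactorCurve",
    "MTCTable",
    "z_factor",
    "group_size_zfactor",
    "rescue_percent",
    "call_hits",
    "target_class_summary",
    "determine_mtc",
    "plate_capacity",
    "assay_qc",
]

DEFAULT_MTC_LADDER = (50.0, 25.0, 10.0, 5.0, 2.0, 1.0, 0.5)  # µM


@dataclass
class CompoundRecord:
    compound_id: str
    target_class: str
    mtc_uM: float
    fish_endpoints: np.ndarray  # VMR light-phase speeds, mm/s
    plate_id: str

    def __post_init__(self) -> None:
        self.fish_endpoints = np.asarray(self.fish_endpoints, dtype=float)
        if self.fish_endpoints.size == 0:
            raise ValueError("endpoint list must be non-empty")


@dataclass
class ScreenDataset:
    """All primary data of one screen run.

    ``plate_controls`` maps plate_id -> (tau_endpoints, sib_endpoints);
    every plate referenced by a compound must carry both control groups.
    """

    compounds: list[CompoundRecord]
    plate_controls: dict[str, tuple[np.ndarray, np.ndarray]]
    group_size: int = 12
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp in self.compounds:
            if comp.plate_id not in self.plate_controls:
                raise ValueError(f"plate {comp.plate_id} lacks control groups")


@dataclass
class ScreenResult:
    compound_ids: list[str]
    target_classes: list[str]
    rescue_percent: np.ndarray   # per compound
    rescue_se: np.ndarray        # per compound
    library_mean: float
    library_sd: float
    hit_threshold: float         # library_mean + 3 * library_sd
    hits: list[str]


@dataclass
class ZFactorCurve:
    group_sizes: list[int]
    zprime_values: dict[int, np.ndarray]  # size -> Z' per random grouping
    mean: dict[int, float]
    sd: dict[int, float]


@dataclass
class MTCTable:
    """Per-compound MTC staging results.

    ``mtc_uM`` is nan for compounds intolerant at every ladder step
    (flagged unusable and excluded from the screening stage).
    """

    compound_ids: list[str]
    mtc_uM: np.ndarray
    usable: np.ndarray  # bool


def z_factor(positive_values: Sequence[float],
             negative_values: Sequence[float]) -> float:
    """Screening-window statistic Z' = 1 - 3(sd_p + sd_n)/|mu_p - mu_n|.

    Sample SDs (n-1); symmetric in arm labels; at most 1.  Returns nan
    when the arm means coincide (undefined window).
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each arm needs at least 2 values")
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        return float("nan")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window


def group_size_zfactor(positive_values: Sequence[float],
                       negative_values: Sequence[float],
                       sizes: Sequence[int] = tuple(range(2, 17)),
                       n_groupings: int = 100,
                       seed: int | np.random.Generator = 0) -> ZFactorCurve:
    """Z' of group-mean endpoints over random disjoint groupings.

    For each group size, each arm is shuffled and partitioned into
    disjoint groups of exactly that size (remainder discarded); Z' is
    computed on the group means.  This is repeated ``n_groupings`` times
    with fresh shuffles.  Size 1 with a single grouping reduces to the
    raw-value Z'.  Sizes too large to yield two groups per arm are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    values: dict[int, np.ndarray] = {}
    kept: list[int] = []
    for size in sizes:
        if size < 1:
            raise ValueError("group size must be >= 1")
        if min(len(pos), len(neg)) < 2 * size:
            warnings.warn(f"group size {size} skipped: needs >= {2 * size} "
                          "values per arm", stacklevel=2)
            continue
        zs = np.empty(n_groupings)
        for i in range(n_groupings):
            gp = _group_means(pos, size, rng)
            gn = _group_means(neg, size, rng)
            zs[i] = z_factor(gp, gn)
        values[size] = zs
        kept.append(size)
    return ZFactorCurve(
        group_sizes=kept,
        zprime_values=values,
        mean={s: float(values[s].mean()) for s in kept},
        sd={s: float(values[s].std(ddof=1)) if n_groupings > 1 else 0.0
            for s in kept},
    )


def _group_means(arm: np.ndarray, size: int,
                 rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(arm)
    n_groups = len(arm) // size
    return perm[: n_groups * size].reshape(n_groups, size).mean(axis=1)


def rescue_percent(compound_mean: float, tau_ctrl_mean: float,
                   sib_ctrl_mean: float) -> float:
    """Linear within-plate rescue normalization.

    Maps the Tau control mean to 0% and the sibling control mean to 100%.
    Controls must come from the same plate as the compound.
    """
    window = sib_ctrl_mean - tau_ctrl_mean
    if window == 0:
        raise ValueError("degenerate phenotypic window (equal control means)")
    # ratio first so the control anchors map to exactly 0 and 100
    return 100.0 * ((compound_mean - tau_ctrl_mean) / window)


def call_hits(screen: ScreenDataset) -> ScreenResult:
    """Score all compounds and call hits at library mean + 3 SD.

    Per-compound rescue uses the compound group's mean endpoint and its
    own plate's controls; the per-compound SE is the SD of the fish
    endpoints rescaled to rescue units over sqrt(n).  The library mean
    and sample SD are taken over all per-compound rescues (no trimming);
    hits strictly exceed the threshold.
    """
    if len(screen.compounds) < 3:
        raise ValueError("need at least 3 compounds to define a library")
    ids, classes, rescues, ses = [], [], [], []
    for comp in screen.compounds:
        tau, sib = screen.plate_controls[comp.plate_id]
        tau_mean = float(np.mean(tau))
        sib_mean = float(np.mean(sib))
        window = sib_mean - tau_mean
        r = rescue_percent(float(comp.fish_endpoints.mean()), tau_mean, sib_mean)
        n = comp.fish_endpoints.size
        sd = comp.fish_endpoints.std(ddof=1) if n > 1 else 0.0
        ses.append(100.0 * sd / abs(window) / np.sqrt(n))
        ids.append(comp.compound_id)
        classes.append(comp.target_class)
        rescues.append(r)
    rescues_arr = np.asarray(rescues)
    lib_mean = float(rescues_arr.mean())
    lib_sd = float(rescues_arr.std(ddof=1))
    threshold = lib_mean + 3.0 * lib_sd
    hits = [ids[i] for i in np.flatnonzero(rescues_arr > threshold)]
    return ScreenResult(
        compound_ids=ids,
        target_classes=classes,
        rescue_percent=rescues_arr,
        rescue_se=np.asarray(ses),
        library_mean=lib_mean,
        library_sd=lib_sd,
        hit_threshold=threshold,
        hits=hits,
    )


def target_class_summary(rescues: Sequence[float],
                         class_labels: Sequence[str]) -> dict[str, dict]:
    """Aggregate per-compound rescues by pharmacological target class.

    Per class: mean, SE, and a two-tailed one-sample t-test of the class
    mean against 0% rescue.  Classes with a single compound are reported
    without a p-value; empty labels are excluded with a warning.
    """
    rescues = np.asarray(rescues, dtype=float)
    labels = np.asarray(class_labels, dtype=object)
    out: dict[str, dict] = {}
    for cls in dict.fromkeys(labels):  # preserve first-seen order
        if not cls:
            warnings.warn("empty target-class label excluded", stacklevel=2)
            continue
        vals = rescues[labels == cls]
        entry = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(vals.size))
                  if vals.size > 1 else float("nan"),
            "p_value": float("nan"),
        }
        if vals.size >= 2:
            entry["p_value"] = float(stats.ttest_1samp(vals, 0.0).pvalue)
        out[str(cls)] = entry
    return out


def determine_mtc(observations: dict[str, list[tuple[float, bool]]],
                  ladder: Sequence[float] = DEFAULT_MTC_LADDER) -> MTCTable:
    """Walk the toxicity ladder to the maximum tolerated concentration.

    ``observations`` maps compound id to (concentration µM, tolerated)
    pairs following the staged protocol: start at the ladder top (50 µM
    by default) and descend while intolerant.  The MTC is the highest
    tolerated concentration; compounds intolerant at every step are
    flagged unusable.  Observations inconsistent with the ladder
    (tolerated at a dose above an intolerant one) are rejected.
    """
    ladder = tuple(ladder)
    if any(b >= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder must be strictly decreasing")
    ids, mtcs, usable = [], [], []
    for cid, obs in observations.items():
        by_conc = dict()
        for conc, tol in obs:
            if conc not in ladder:
                raise ValueError(f"{cid}: concentration {conc} not on ladder")
            by_conc[conc] = bool(tol)
        tol_concs = [c for c, t in by_conc.items() if t]
        intol_concs = [c for c, t in by_conc.items() if not t]
        if tol_concs and intol_concs and max(tol_concs) > min(intol_concs):
            raise ValueError(f"{cid}: tolerated above an intolerant dose")
        ids.append(cid)
        if tol_concs:
            mtcs.append(max(tol_concs))
            usable.append(True)
        else:
            mtcs.append(float("nan"))
            usable.append(False)
    return MTCTable(compound_ids=ids, mtc_uM=np.asarray(mtcs),
                    usable=np.asarray(usable, dtype=bool))


def plate_capacity(n_wells: int = 96, group_size: int = 12,
                   n_control_groups: int = 2) -> int:
    """Compounds testable per plate alongside the control groups."""
    if group_size <= 0 or n_wells % group_size != 0:
        raise ValueError("group_size must divide the well count")
    capacity = n_wells // group_size - n_control_groups
    if capacity <= 0:
        raise ValueError("no room for compounds at this group size")
    return capacity


def assay_qc(tau_ctrl_endpoints: Sequence[float],
             sib_ctrl_endpoints: Sequence[float],
             min_window: float = 0.3,
             min_fish: int = 6) -> tuple[bool, list[str]]:
    """Within-plate assay quality gate.

    Fails if the sibling mean does not exceed the Tau mean (inverted or
    absent window), if the window is narrower than ``min_window`` (in
    endpoint units, mm/s), or if either control group has fewer than
    ``min_fish`` fish after tracking QC.  Failing plates are excluded
    from hit calling.  Returns (passed, reasons).
    """
    tau = np.asarray(tau_ctrl_endpoints, dtype=float)
    sib = np.asarray(sib_ctrl_endpoints, dtype=float)
    reasons: list[str] = []
    if tau.size < min_fish or sib.size < min_fish:
        reasons.append(f"fewer than {min_fish} fish in a control group")
    if tau.size and sib.size:
        window = sib.mean() - tau.mean()
        if window <= 0:
            reasons.append("inverted phenotypic window (sib mean <= tau mean)")
        elif window < min_window:
            reasons.append(f"phenotypic window {window:.3g} below minimum "
                           f"{min_window}")
    else:
        reasons.append("empty control group")
    return (len(reasons) == 0, reasons)
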