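"""Surveillance and motility metrics from per-frame cell masks.

The central quantity is the per-transition pixel-change map: voxels newly
occupied between consecutive frames are process extensions (PE), voxels
vacated are process retractions (PR).  Their sum per transition is the raw
surveillance index — a proxy for the tissue volume scanned by microglial
processes — which is normalized to its mean over a baseline window (the first
10 min by default).  Dividing by mean projected cell area yields the
cell-size-independent motility index.  Supporting metrics: cumulative
surveilled area and its extrapolated delay between conditions, the stationary
(always-occupied) process area, and the convex-hull territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .core import CellMaskSeries


@dataclass
class PixelChangeMaps:
    """Binary gain/loss maps for one frame transition."""

    PE: np.ndarray  # voxels gained at t -> t+1
    PR: np.ndarray  # voxels lost

    @property
    def n_pe(self) -> int:
        return int(np.count_nonzero(self.PE))

    @property
    def n_pr(self) -> int:
        return int(np.count_nonzero(self.PR))


def pixel_change_maps(mask_t: np.ndarray, mask_t1: np.ndarray) -> PixelChangeMaps:
    """PE = mask_t1 \\ mask_t; PR = mask_t \\ mask_t1 (exact set differences)."""
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_t1 = np.asarray(mask_t1, dtype=bool)
    if mask_t.shape != mask_t1.shape:
        raise ValueError(f"mask shapes differ: {mask_t.shape} vs {mask_t1.shape}")
    return PixelChangeMaps(PE=mask_t1 & ~mask_t, PR=mask_t & ~mask_t1)


class StaticBaselineError(RuntimeError):
    """Raised when the baseline window shows no process movement at all."""


@dataclass
class SurveillanceTrace:
    """Per-transition surveillance index with its baseline normalization.

    ``transition_times_min[i]`` is the time of the *end* frame of transition i.
    ``cell_area_um2[t]`` is the max-z-projected cell area at frame t.
    """

    raw: np.ndarray  # |PE| + |PR| per transition, voxels
    normalized: np.ndarray
    transition_times_min: np.ndarray
    baseline_window_min: tuple[float, float]
    cell_area_um2: np.ndarray
    n_pe: np.ndarray
    n_pr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.transition_times_min,
                "n_pe": self.n_pe,
                "n_pr": self.n_pr,
                "raw": self.raw,
                "normalized": self.normalized,
            }
        )


def surveillance_trace(
    masks: CellMaskSeries,
    baseline_minutes: tuple[float, float] = (1.0, 10.0),
) -> SurveillanceTrace:
    """Raw and baseline-normalized surveillance index per frame transition.

    The raw index of transition t→t+1 is ``|PE| + |PR|`` in voxels; the
    normalized index divides by the mean raw index over transitions whose end
    time falls inside ``baseline_minutes``.  A completely static baseline is
    an error: the normalization is undefined.
    """
    if masks.n_frames < 2:
        raise ValueError("need at least 2 frames")
    n_trans = masks.n_frames - 1
    times = masks.frame_times_min[1:]
    n_pe = np.empty(n_trans, dtype=int)
    n_pr = np.empty(n_trans, dtype=int)
    for t in range(n_trans):
        maps = pixel_change_maps(masks.masks[t], masks.masks[t + 1])
        n_pe[t], n_pr[t] = maps.n_pe, maps.n_pr
    raw = (n_pe + n_pr).astype(float)

    lo, hi = baseline_minutes
    in_base = (times >= lo) & (times <= hi)
    if not in_base.any():
        raise ValueError("baseline window covers no transition")
    base_mean = raw[in_base].mean()
    if base_mean == 0:
        raise StaticBaselineError("baseline window contains no process movement; index undefined")
    areas = np.array([masks.projection(t).sum() * masks.pixel_area_um2 for t in range(masks.n_frames)])
    return SurveillanceTrace(
        raw=raw,
        normalized=raw / base_mean,
        transition_times_min=times,
        baseline_window_min=(lo, hi),
        cell_area_um2=areas,
        n_pe=n_pe,
        n_pr=n_pr,
    )


def effect_index(trace: SurveillanceTrace, window_minutes: tuple[float, float] = (35.0, 40.0)) -> float:
    """Mean normalized surveillance index over an effect window (e.g. the last
    five minutes of drug exposure)."""
    lo, hi = window_minutes
    sel = (trace.transition_times_min >= lo) & (trace.transition_times_min <= hi)
    if not sel.any():
        raise ValueError("effect window covers no transition")
    return float(trace.normalized[sel].mean())


def motility_index(
    trace: SurveillanceTrace,
    window_minutes: tuple[float, float] | None = None,
) -> float:
    """Surveillance index divided by mean projected cell area (voxels/μm²).

    Normalizing by cell area removes the trivial dependence of voxel turnover
    on cell size, leaving a measure of how dynamic the processes themselves
    are.  Computed over ``window_minutes`` (default: the whole recording).
    """
    if window_minutes is None:
        sel_t = np.ones_like(trace.raw, dtype=bool)
        sel_a = np.ones_like(trace.cell_area_um2, dtype=bool)
    else:
        lo, hi = window_minutes
        sel_t = (trace.transition_times_min >= lo) & (trace.transition_times_min <= hi)
        frame_times = np.concatenate([[2 * trace.transition_times_min[0] - trace.transition_times_min[1]
                                       if len(trace.transition_times_min) > 1 else 0.0],
                                      trace.transition_times_min])
        sel_a = (frame_times >= lo) & (frame_times <= hi)
        if not sel_a.any():
            sel_a = sel_t.copy()
    if not sel_t.any():
        raise ValueError("window covers no transition")
    mean_area = trace.cell_area_um2[sel_a].mean() if sel_a.any() else trace.cell_area_um2.mean()
    if mean_area <= 0:
        raise ValueError("mean cell area is zero")
    return float(trace.raw[sel_t].mean() / mean_area)


@dataclass
class CumulativeAreaResult:
    times_min: np.ndarray
    cumulative_area_um2: np.ndarray  # union of projections from window start to t
    rate_um2_per_min: float


def cumulative_area(
    masks: CellMaskSeries,
    window_minutes: tuple[float, float] = (0.0, 15.0),
) -> CumulativeAreaResult:
    """Cumulatively surveilled projected area over a window.

    The value at time t is the area of the union of max-z projections from the
    window start up to t (non-decreasing by construction).  The surveillance
    rate is the final cumulative area divided by the window duration.
    """
    lo, hi = window_minutes
    sel = np.where((masks.frame_times_min >= lo) & (masks.frame_times_min <= hi))[0]
    if len(sel) < 2:
        raise ValueError("window must contain at least 2 frames")
    union = np.zeros_like(masks.projection(0))
    areas = np.empty(len(sel))
    for k, t in enumerate(sel):
        union |= masks.projection(t)
        areas[k] = union.sum() * masks.pixel_area_um2
    times = masks.frame_times_min[sel]
    duration = times[-1] - times[0]
    return CumulativeAreaResult(
        times_min=times,
        cumulative_area_um2=areas,
        rate_um2_per_min=float(areas[-1] / duration) if duration > 0 else np.nan,
    )


def surveillance_delay(
    reference: CumulativeAreaResult,
    slower: CumulativeAreaResult,
    t_ref_min: float = 15.0,
) -> float:
    """Extrapolated delay (%) for the slower condition to reach the reference
    condition's cumulative area at ``t_ref_min``.

    A least-squares line is fitted to the final third of the slower trace and
    extrapolated forward to the reference's area at ``t_ref_min``; the delay is
    the extra time needed, as a percentage of ``t_ref_min``.
    """
    ref_area = float(np.interp(t_ref_min, reference.times_min, reference.cumulative_area_um2))
    t, a = slower.times_min, slower.cumulative_area_um2
    if a[-1] >= ref_area:
        # already reached within the window: interpolate the crossing time
        t_cross = float(np.interp(ref_area, a, t))
        return (t_cross - t_ref_min) / t_ref_min * 100.0
    k = max(2, len(t) // 3)
    slope, intercept = np.polyfit(t[-k:], a[-k:], 1)
    if slope <= 0:
        return float("inf")
    t_cross = (ref_area - intercept) / slope
    return (t_cross - t_ref_min) / t_ref_min * 100.0


def stationary_area(
    masks: CellMaskSeries,
    window_minutes: tuple[float, float] = (0.0, 15.0),
) -> float:
    """Area (μm²) of processes present in *every* frame of the window, soma
    excluded.

    For binary masks the minimum-intensity projection over time is the
    temporal intersection of the per-frame max-z projections: exactly the
    always-occupied, non-motile part of the cell.
    """
    lo, hi = window_minutes
    sel = np.where((masks.frame_times_min >= lo) & (masks.frame_times_min <= hi))[0]
    if len(sel) < 2:
        raise ValueError("window must contain at least 2 frames")
    persistent = np.ones_like(masks.projection(0))
    for t in sel:
        persistent &= masks.projection(t)
    persistent &= ~masks.soma.any(axis=0)
    return float(persistent.sum() * masks.pixel_area_um2)


def territory(mask: np.ndarray, voxel_size_xy: float) -> float:
    """Convex-hull territory (μm²) of one 3D mask.

    Area of the 2D convex hull of the max-z projection — the smallest convex
    polygon enclosing all distal process tips.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        proj = mask.any(axis=0)
    else:
        proj = mask
    pts = np.argwhere(proj).astype(float)
    if len(pts) == 0:
        raise ValueError("empty mask")
    # hull of projected pixel centres; collinear masks enclose zero area
    try:
        hull = ConvexHull(pts * voxel_size_xy)
    except QhullError:
        return 0.0
    return float(hull.volume)  # 2D hull: "volume" is the polygon area


def territory_volume(mask: np.ndarray, voxel_size_xy: float, voxel_size_z: float) -> float:
    """3D convex-hull volume (μm³) of the mask, as an optional 3D variant."""
    pts = np.argwhere(np.asarray(mask, dtype=bool)).astype(float)
    if len(pts) == 0:
        raise ValueError("empty mask")
    scaled = pts * [voxel_size_z, voxel_size_xy, voxel_size_xy]
    try:
        return float(ConvexHull(scaled).volume)
    except QhullError as e:
        raise ValueError("mask too flat for a 3D hull") from e
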