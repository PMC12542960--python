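"""Chemotaxis quantification: radial-sector clear area and its monoexponential
time constant.

After a focal laser ablation, microglial processes converge on the lesion.
The image around the ablation centre is divided into radial sectors; in each
sector the process front is the nearest mask pixel to the centre, and the
"clear area" not yet covered by processes is the sum of circular-sector areas
at the per-sector front distances.  The clear area decays approximately
monoexponentially, C(t) = A_inf + (A0 - A_inf)·exp(-t/τ); τ summarizes how
fast the response converges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import CellMaskSeries


@dataclass
class ClearAreaTrace:
    times_s: np.ndarray
    clear_area_um2: np.ndarray
    center_px: tuple[float, float]  # (y, x)
    n_sectors: int
    radius_um: float

    @property
    def times_min(self) -> np.ndarray:
        return self.times_s / 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "clear_area_um2": self.clear_area_um2})


def clear_area(
    mask: np.ndarray,
    center_px: tuple[float, float],
    n_sectors: int = 36,
    radius_um: float = 50.0,
    pixel_size_um: float = 1.0,
) -> float:
    """Clear area (μm²) around ``center_px`` for one (projected) mask.

    3D masks are max-z projected first.  Per sector the front distance is the
    minimum centre-to-pixel distance (capped at ``radius_um``; sectors without
    any mask pixel contribute the full sector out to ``radius_um``), and the
    clear area is the sum of circular-sector areas (Δθ/2)·d².
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        mask = mask.any(axis=0)
    if n_sectors < 4:
        raise ValueError("need n_sectors >= 4")
    cy, cx = center_px
    if not (0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1]):
        raise ValueError("center outside image")
    lim = min(cy, mask.shape[0] - 1 - cy, cx, mask.shape[1] - 1 - cx) * pixel_size_um
    if radius_um > lim:
        raise ValueError(f"analysis radius {radius_um} μm exceeds image bounds ({lim:.1f} μm)")
    fronts = _sector_fronts(mask, (cy, cx), n_sectors, radius_um, pixel_size_um)
    dtheta = 2 * math.pi / n_sectors
    return float((dtheta / 2.0) * np.sum(fronts**2))


def _sector_fronts(
    mask: np.ndarray,
    center_px: tuple[float, float],
    n_sectors: int,
    radius_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Per-sector minimum distance (μm) from centre to a mask pixel, capped at radius.

    Each pixel is credited to every sector its finite footprint overlaps
    (half-angle atan(0.6·pixel/d)), so fronts stay well-defined when sectors
    are narrower than the angular spacing of pixels."""
    cy, cx = center_px
    ys, xs = np.nonzero(mask)
    fronts = np.full(n_sectors, radius_um)
    if len(ys) == 0:
        return fronts
    dy = (ys - cy) * pixel_size_um
    dx = (xs - cx) * pixel_size_um
    dist = np.hypot(dy, dx)
    width = 2 * math.pi / n_sectors
    theta = np.arctan2(dy, dx) % (2 * math.pi)
    half = np.arctan2(0.6 * pixel_size_um, dist)  # pi/2 for the centre pixel itself
    s_lo = np.floor((theta - half) / width).astype(int)
    s_hi = np.floor((theta + half) / width).astype(int)
    span = s_hi - s_lo
    for k in range(int(span.max()) + 1):
        sel = span >= k
        idx = (s_lo[sel] + k) % n_sectors
        np.minimum.at(fronts, idx, dist[sel])
    return fronts


def clear_area_trace(
    masks: CellMaskSeries | np.ndarray,
    center_px: tuple[float, float],
    n_sectors: int = 36,
    radius_um: float = 50.0,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ClearAreaTrace:
    """Clear area per frame; masks are max-z projections of (reduced) z-stacks."""
    if isinstance(masks, CellMaskSeries):
        frames = masks.masks
        pixel_size_um = masks.voxel_size_xy
        frame_interval_s = masks.frame_interval_s
    else:
        frames = np.asarray(masks, dtype=bool)
        if pixel_size_um is None or frame_interval_s is None:
            raise ValueError("raw arrays need pixel_size_um and frame_interval_s")
    if frames.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    areas = np.array(
        [clear_area(frames[t], center_px, n_sectors, radius_um, pixel_size_um) for t in range(frames.shape[0])]
    )
    return ClearAreaTrace(
        times_s=np.arange(frames.shape[0]) * frame_interval_s,
        clear_area_um2=areas,
        center_px=tuple(center_px),
        n_sectors=n_sectors,
        radius_um=radius_um,
    )


@dataclass
class TauFit:
    """Monoexponential fit C(t) = A_inf + (A0 - A_inf)·exp(-t/τ)."""

    tau_min: float
    A0_um2: float
    A_inf_um2: float
    residual_rms: float
    converged: bool


def fit_tau(trace: ClearAreaTrace, truncate_at_plateau: bool = False) -> TauFit:
    """Least-squares monoexponential fit of the clear-area decay; τ in minutes.

    Initialized with A0 = first value, A_inf = last value and τ = time to
    half-decay; τ is bounded to (0, 10× recording length].  Non-convergence
    (including traces with no decay, where τ is unidentifiable) is flagged,
    not raised.  ``truncate_at_plateau`` drops points after the trace first
    reaches its minimum.
    """
    t = trace.times_min
    c = trace.clear_area_um2.astype(float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if truncate_at_plateau:
        stop = int(np.argmin(c)) + 1
        if stop >= 5:
            t, c = t[:stop], c[:stop]

    a0, ainf = float(c[0]), float(c[-1])
    span = a0 - ainf
    if span <= 0 or span < 1e-9 * max(abs(a0), 1.0):
        return TauFit(tau_min=math.inf, A0_um2=a0, A_inf_um2=ainf, residual_rms=float(np.std(c)), converged=False)
    half = ainf + span / 2.0
    below = np.nonzero(c <= half)[0]
    tau0 = float(t[below[0]]) / math.log(2) if len(below) and t[below[0]] > 0 else (t[-1] - t[0]) / 4.0
    tau0 = min(max(tau0, 1e-3), 10.0 * (t[-1] - t[0]))

    def model(tt, a_inf, amp, tau):
        return a_inf + amp * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            t,
            c,
            p0=[ainf, span, tau0],
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, 10.0 * max(t[-1], 1.0)]),
            maxfev=10000,
        )
    except RuntimeError:
        return TauFit(tau_min=math.nan, A0_um2=a0, A_inf_um2=ainf, residual_rms=math.nan, converged=False)
    a_inf_fit, amp_fit, tau_fit = popt
    resid = c - model(t, *popt)
    return TauFit(
        tau_min=float(tau_fit),
        A0_um2=float(a_inf_fit + amp_fit),
        A_inf_um2=float(a_inf_fit),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )
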