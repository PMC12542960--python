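"""Image preprocessing: background subtraction, median filtering, rigid 4D
drift correction, and seeded per-cell binarization.

Drift is modelled as a per-frame rigid integer-voxel translation (no
rotation): lateral (y, x) shifts are estimated by cross-correlation of
maximum-z projections against a reference frame, then the axial (z) shift from
(z, x) projections.  Manual cell selection is replaced by a reproducible
seed-point rule: threshold (Otsu within a dilated bounding box around the
seed), then keep the 26-connected component containing the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .core import CellMaskSeries, ImageStack4D

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def preprocess_stack(
    stack: ImageStack4D,
    background_percentile: float = 10.0,
    median_radius: int = 1,
) -> ImageStack4D:
    """Subtract a per-frame constant background and median-filter each z-plane.

    The background estimate is the given low percentile of each frame's
    intensities; subtraction is clipped at zero.  ``median_radius = 0``
    disables filtering.
    """
    if not (0 <= background_percentile < 100):
        raise ValueError("background_percentile must be in [0, 100)")
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    out = np.empty_like(stack.data, dtype=float)
    size = 2 * median_radius + 1
    for t in range(stack.n_frames):
        frame = stack.data[t].astype(float)
        bg = np.percentile(frame, background_percentile)
        frame = np.clip(frame - bg, 0.0, None)
        if median_radius > 0:
            for z in range(frame.shape[0]):
                frame[z] = ndimage.median_filter(frame[z], size=size)
        out[t] = frame
    return stack.copy_with(out, background_percentile=background_percentile, median_radius=median_radius)


@dataclass
class DriftResult:
    stack: ImageStack4D
    shifts: pd.DataFrame  # columns frame, dz, dy, dx, confidence, low_confidence


def correct_drift(
    stack: ImageStack4D,
    reference_frame: int = 0,
    confidence_threshold: float = 0.1,
) -> DriftResult:
    """Rigidly align every frame to ``reference_frame``.

    Estimated shifts are rounded to integer voxels and undone by translation.
    ``confidence`` is the normalized cross-correlation of the aligned frame's
    max-z projection with the reference; frames below ``confidence_threshold``
    are flagged ``low_confidence``.  A warning (not an error) is issued when a
    shift exceeds 10% of the field of view.
    """
    if not (0 <= reference_frame < stack.n_frames):
        raise ValueError("reference_frame out of range")
    data = stack.data.astype(float)
    ref = data[reference_frame]
    ref_xy = ref.max(axis=0)
    ref_zx = ref.max(axis=1)
    out = np.empty_like(data)
    rows = []
    for t in range(stack.n_frames):
        frame = data[t]
        (dy, dx), _, _ = phase_cross_correlation(ref_xy, frame.max(axis=0), upsample_factor=1, normalization=None)
        (dz, _), _, _ = phase_cross_correlation(ref_zx, frame.max(axis=1), upsample_factor=1, normalization=None)
        shift = np.round([dz, dy, dx]).astype(int)
        if np.any(np.abs(shift[1:]) > 0.1 * np.array(frame.shape[1:])):
            warnings.warn(f"frame {t}: estimated drift {shift.tolist()} exceeds 10% of field of view")
        aligned = ndimage.shift(frame, shift, order=0, mode="constant", cval=float(frame.min()))
        out[t] = aligned
        conf = _ncc(ref_xy, aligned.max(axis=0))
        rows.append(
            {
                "frame": t,
                "dz": int(shift[0]),
                "dy": int(shift[1]),
                "dx": int(shift[2]),
                "confidence": conf,
                "low_confidence": bool(conf < confidence_threshold),
            }
        )
    shifts = pd.DataFrame(rows)
    return DriftResult(stack=stack.copy_with(out, drift_corrected=True), shifts=shifts)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


class EmptyCellError(RuntimeError):
    """Raised when binarization finds no cell component at some frame."""

    def __init__(self, frame: int):
        self.frame = frame
        super().__init__(f"no cell component containing the seed at frame {frame}")


def binarize_cell(
    stack: ImageStack4D,
    seed_point: tuple[int, int, int],
    method: str = "otsu",
    threshold: float | None = None,
    bbox_dilation: int = 10,
) -> CellMaskSeries:
    """Segment one cell per frame from a seed voxel (z, y, x).

    Per frame: threshold the stack (Otsu computed within a dilated bounding
    box around the seed's component at frame 0, or a fixed/percentile
    threshold), then keep the 26-connected component containing the seed.
    The soma is the largest inscribed sphere around the cell's
    intensity-weighted centroid at frame 0, intersected with every frame's
    mask to preserve containment.
    """
    seed_point = tuple(int(c) for c in seed_point)
    frame0 = stack.data[0].astype(float)
    thr0 = _resolve_threshold(frame0, method, threshold)
    rough = frame0 > thr0
    if not rough[seed_point]:
        raise EmptyCellError(0)
    lbl, _ = ndimage.label(rough, structure=STRUCT_26)
    comp = lbl == lbl[seed_point]
    bbox = ndimage.find_objects(comp.astype(int))[0]
    bbox = tuple(
        slice(max(0, s.start - bbox_dilation), min(n, s.stop + bbox_dilation))
        for s, n in zip(bbox, frame0.shape)
    )

    masks = np.zeros(stack.data.shape, dtype=bool)
    for t in range(stack.n_frames):
        frame = stack.data[t].astype(float)
        thr = _resolve_threshold(frame[bbox], method, threshold)
        binary = frame > thr
        if not binary[seed_point]:
            raise EmptyCellError(t)
        lbl, _ = ndimage.label(binary, structure=STRUCT_26)
        masks[t] = lbl == lbl[seed_point]

    soma = estimate_soma(masks[0], frame0, stack.voxel_size_xy, stack.voxel_size_z)
    soma = soma & masks.all(axis=0)
    return CellMaskSeries(
        masks=masks,
        soma=soma,
        voxel_size_xy=stack.voxel_size_xy,
        voxel_size_z=stack.voxel_size_z,
        frame_interval_s=stack.frame_interval_s,
    )


def _resolve_threshold(frame: np.ndarray, method: str, threshold: float | None) -> float:
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires an explicit threshold")
        return float(threshold)
    if method == "percentile":
        return float(np.percentile(frame, threshold if threshold is not None else 99.0))
    if method == "otsu":
        return float(threshold_otsu(frame))
    raise ValueError(f"unknown threshold method {method!r}")


def estimate_soma(
    mask: np.ndarray,
    intensities: np.ndarray,
    voxel_size_xy: float,
    voxel_size_z: float,
) -> np.ndarray:
    """Soma = largest inscribed sphere of the mask near its intensity-weighted
    centroid, found via the anisotropy-aware Euclidean distance transform."""
    if not mask.any():
        return np.zeros_like(mask)
    edt = ndimage.distance_transform_edt(mask, sampling=(voxel_size_z, voxel_size_xy, voxel_size_xy))
    w = np.where(mask, intensities, 0.0)
    centroid = np.array(ndimage.center_of_mass(w)) if w.sum() > 0 else np.array(ndimage.center_of_mass(mask))
    # pick the EDT maximum, breaking ties toward the centroid
    cand = np.argwhere(edt >= edt.max() * 0.999)
    d2c = np.linalg.norm((cand - centroid) * [voxel_size_z, voxel_size_xy, voxel_size_xy], axis=1)
    center = cand[int(np.argmin(d2c))]
    radius = float(edt[tuple(center)])
    zz, yy, xx = np.indices(mask.shape)
    dist2 = (
        ((zz - center[0]) * voxel_size_z) ** 2
        + ((yy - center[1]) * voxel_size_xy) ** 2
        + ((xx - center[2]) * voxel_size_xy) ** 2
    )
    return (dist2 <= radius**2) & mask
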