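"""Ground-truthed 4D simulator of ramified microglia.

The simulator builds a geometric cell model (spherical soma plus a rooted tree
of tubular branches), rasterizes it into anisotropic voxel grids matching
two-photon acquisition settings (by default 50-μm stacks at 2-μm z-steps every
60 s for surveillance, or 25-μm stacks every 30 s for chemotaxis, over a
258-μm square field of view), and animates process tips with configurable
extension/retraction dynamics.  Every simulation returns the noiseless truth
masks and truth metrics (branch count, total branch length, per-transition
gained/lost voxel counts, the chemotactic clear-area decay) computed from the
model geometry — never from the rendered images — so that downstream analysis
can be validated against known ground truth.

Randomness is fully determined by integer seeds: identical seeds give
bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import CellMaskSeries, ImageStack4D

__all__ = [
    "Branch",
    "CellModel",
    "NoiseModel",
    "AcquisitionConfig",
    "TipDynamics",
    "SimulationResult",
    "build_cell_model",
    "render_cell",
    "simulate_surveillance",
    "simulate_chemotaxis",
    "inject_artifacts",
]


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    """One tubular branch: a polyline of 3D nodes (μm, zyx) with a radius."""

    points: np.ndarray  # (n_nodes, 3) μm, zyx, first point at attachment
    radius: float  # μm
    parent: int  # index of parent branch, -1 for primary branches
    depth: int  # 0 for primary branches

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CellModel:
    """Geometric microglia model: soma sphere + rooted branch tree.

    Coordinates are micrometres in the cell frame; ``soma_center`` is placed at
    the centre of the simulated volume when rendered.
    """

    soma_center: np.ndarray
    soma_radius: float
    branches: list[Branch]

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        if self.soma_radius <= 0:
            raise ValueError("soma_radius must be positive")
        for b in self.branches:
            if b.radius <= 0:
                raise ValueError("branch radii must be positive")

    @property
    def n_primary(self) -> int:
        return sum(1 for b in self.branches if b.parent == -1)

    @property
    def P_true(self) -> int:
        """Ground-truth number of primary processes."""
        return self.n_primary

    @property
    def L_true(self) -> float:
        """Ground-truth total process length (μm)."""
        return sum(b.length for b in self.branches)

    def terminal_branches(self) -> list[int]:
        has_child = {b.parent for b in self.branches}
        return [i for i in range(len(self.branches)) if i not in has_child]

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of the model's bounding box in μm (zyx)."""
        pts = [self.soma_center - self.soma_radius, self.soma_center + self.soma_radius]
        for b in self.branches:
            pts.append(b.points.min(axis=0) - b.radius)
            pts.append(b.points.max(axis=0) + b.radius)
        pts = np.asarray(pts)
        return pts.min(axis=0), pts.max(axis=0)


@dataclass
class NoiseModel:
    """Poisson photon noise plus additive Gaussian read noise.

    ``photon_scale`` converts intensity units to expected photon counts; the
    Poisson draw is made at that scale and converted back.  ``read_noise_sd``
    is in intensity units.
    """

    photon_scale: float = 0.5
    read_noise_sd: float = 2.0

    def apply(self, frame: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = frame.astype(float)
        if self.photon_scale > 0:
            out = rng.poisson(np.maximum(out, 0) * self.photon_scale) / self.photon_scale
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass
class AcquisitionConfig:
    """Voxel grid, timing and noise settings of a simulated acquisition."""

    voxel_size_xy: float = 258.0 / 512.0
    voxel_size_z: float = 2.0
    stack_depth: float = 50.0
    fov_xy: float = 258.0
    frame_interval_s: float = 60.0
    n_frames: int = 41
    intensity_cell: float = 100.0
    intensity_bg: float = 5.0
    noise_model: NoiseModel | None = field(default_factory=NoiseModel)
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxels, zyx
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_size_xy", "voxel_size_z", "stack_depth", "fov_xy", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @classmethod
    def surveillance(cls, **kw) -> "AcquisitionConfig":
        """50-μm stacks, 2-μm z-steps, one frame per minute."""
        return cls(**{"stack_depth": 50.0, "voxel_size_z": 2.0, "frame_interval_s": 60.0, **kw})

    @classmethod
    def chemotaxis(cls, **kw) -> "AcquisitionConfig":
        """25-μm stacks, 2-μm z-steps, one frame every 30 s."""
        return cls(**{"stack_depth": 25.0, "voxel_size_z": 2.0, "frame_interval_s": 30.0, **kw})

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nz = max(1, round(self.stack_depth / self.voxel_size_z))
        nxy = max(1, round(self.fov_xy / self.voxel_size_xy))
        return nz, nxy, nxy

    @property
    def spacings(self) -> np.ndarray:
        return np.array([self.voxel_size_z, self.voxel_size_xy, self.voxel_size_xy])

    def um_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Cell-frame μm coordinates → fractional voxel indices (origin at volume centre)."""
        shape = np.array(self.grid_shape, dtype=float)
        return np.atleast_2d(points_um) / self.spacings + (shape - 1) / 2.0


@dataclass
class TipDynamics:
    """Per-tip extension/retraction behaviour.

    Tip speeds (μm/min) are drawn per terminal branch from
    ``N(mean_speed, speed_sd)`` truncated at zero; each tip oscillates between
    ``min_frac`` and ``max_frac`` of its initial length, reflecting at the
    bounds.  An optional global slowdown (``slowdown_factor`` applied from
    ``slowdown_start_min`` onwards) models acute pharmacological blockade.
    """

    mean_speed: float = 2.0
    speed_sd: float = 0.5
    min_frac: float = 0.3
    max_frac: float = 1.25
    slowdown_factor: float = 1.0
    slowdown_start_min: float | None = None
    start_frac: float | None = None  # fixed initial tip length fraction (else random phase)
    start_sign: float | None = None  # fixed initial direction: +1 extend, -1 retract

    def factor_at(self, t_min: float) -> float:
        if self.slowdown_start_min is not None and t_min >= self.slowdown_start_min:
            return self.slowdown_factor
        return 1.0


@dataclass
class SimulationResult:
    stack: ImageStack4D
    truth_masks: CellMaskSeries
    truth_metrics: dict


# ---------------------------------------------------------------------------
# Cell model construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def build_cell_model(
    n_primary: int,
    branch_prob: float,
    length_scale: float,
    seed: int,
    *,
    soma_radius: float = 4.0,
    branch_radius: float = 1.2,
    n_seg: int = 4,
    max_depth: int = 3,
    child_decay: float = 0.6,
    jitter: float = 0.25,
    z_flatten: float = 0.15,
) -> CellModel:
    """Grow a rooted microglia-like branch tree.

    Primary branches leave the soma at evenly spread azimuths (small random
    jitter) and mostly laterally (|z-component| ≤ ``z_flatten``), matching
    cells imaged in thin cortical stacks.  Each branch is a polyline of
    ``n_seg`` equal-length segments summing exactly to its nominal length
    (``length_scale`` at depth 0, decaying by ``child_decay`` per generation),
    with small angular jitter between segments.  After finishing a branch's
    polyline, one uniform draw decides (probability ``branch_prob``, only while
    ``depth < max_depth``) whether two children sprout at its tip.

    All randomness comes from ``numpy.random.default_rng(seed)`` as uniform
    draws in a fixed pre-order traversal, so the branching process can be
    replayed draw-for-draw.
    """
    if n_primary < 1:
        raise ValueError("n_primary must be >= 1")
    if not (0 <= branch_prob < 1):
        raise ValueError("branch_prob must be in [0, 1)")
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")

    rng = np.random.default_rng(seed)
    branches: list[Branch] = []

    def _dir(phi: float, slope: float) -> np.ndarray:
        # unit direction from azimuth and bounded z-slope; |z-component| of the
        # *displacement* per unit length is slope/sqrt(1+slope^2) <= slope, so
        # the whole tree stays within z_flatten times the total path length
        return _unit(np.array([slope, math.sin(phi), math.cos(phi)]))

    def grow(start: np.ndarray, phi: float, slope: float, depth: int, length: float, parent: int) -> None:
        pts = [start]
        seg_len = length / n_seg
        for s in range(n_seg):
            if s > 0:
                phi += (rng.random() - 0.5) * 2 * jitter
            pts.append(pts[-1] + _dir(phi, slope) * seg_len)
        idx = len(branches)
        branches.append(Branch(points=np.asarray(pts), radius=branch_radius * (0.8**depth), parent=parent, depth=depth))
        if depth < max_depth and rng.random() < branch_prob:
            tip = pts[-1]
            for c, sign in enumerate((1.0, -1.0)):
                alpha = 0.5 + 0.5 * rng.random()  # 29°–57° azimuthal divergence
                child_slope = (rng.random() - 0.5) * 2 * z_flatten
                grow(tip, phi + sign * alpha, child_slope, depth + 1, length * child_decay, idx)

    for i in range(n_primary):
        phi = 2 * math.pi * (i + 0.5 * rng.random()) / n_primary
        slope = (rng.random() - 0.5) * 2 * z_flatten
        direction = _dir(phi, slope)
        start = np.zeros(3) + soma_radius * direction
        grow(start, phi, slope, 0, length_scale, -1)

    return CellModel(soma_center=np.zeros(3), soma_radius=soma_radius, branches=branches)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _paint_capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float, acq: AcquisitionConfig) -> None:
    """Set voxels whose centre lies within ``radius`` μm of segment p0–p1."""
    spac = acq.spacings
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    lo_idx = np.maximum(np.floor(acq.um_to_index(lo)[0]).astype(int), 0)
    hi_idx = np.minimum(np.ceil(acq.um_to_index(hi)[0]).astype(int) + 1, np.array(mask.shape))
    if np.any(lo_idx >= hi_idx):
        return
    ranges = [np.arange(lo_idx[a], hi_idx[a]) for a in range(3)]
    shape = np.array(mask.shape, dtype=float)
    coords = [(r - (shape[a] - 1) / 2.0) * spac[a] for a, r in enumerate(ranges)]
    Z, Y, X = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([Z, Y, X], axis=-1)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    rel = pts - p0
    if seg_len2 > 0:
        tproj = np.clip((rel @ seg) / seg_len2, 0.0, 1.0)
    else:
        tproj = np.zeros(pts.shape[:-1])
    closest = p0 + tproj[..., None] * seg
    dist2 = ((pts - closest) ** 2).sum(axis=-1)
    sub = dist2 <= radius**2
    mask[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] |= sub


def _truncated_polyline(branch: Branch, length: float) -> np.ndarray:
    """Polyline of ``branch`` cut (or extended along its last segment) to ``length`` μm."""
    pts = branch.points
    seg_vecs = np.diff(pts, axis=0)
    seg_lens = np.linalg.norm(seg_vecs, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_lens)])
    if length >= cum[-1]:
        d = seg_vecs[-1] / seg_lens[-1]
        tip = pts[-1] + d * (length - cum[-1])
        return np.vstack([pts, tip])
    out = [pts[0]]
    for i in range(len(seg_lens)):
        if cum[i + 1] < length:
            out.append(pts[i + 1])
        else:
            frac = (length - cum[i]) / seg_lens[i]
            out.append(pts[i] + frac * seg_vecs[i])
            break
    return np.asarray(out)


def render_cell(
    model: CellModel,
    acq: AcquisitionConfig,
    tip_lengths: dict[int, float] | None = None,
) -> np.ndarray:
    """Rasterize the model into a boolean ``(z, y, x)`` volume.

    ``tip_lengths`` overrides the current length of terminal branches (μm along
    the polyline from the attachment point).  Raises if any rendered geometry
    would leave the simulated volume.
    """
    shape = acq.grid_shape
    half = (np.array(shape) - 1) / 2.0 * acq.spacings + acq.spacings / 2.0
    mask = np.zeros(shape, dtype=bool)
    sc = model.soma_center
    _paint_capsule(mask, sc, sc, model.soma_radius, acq)
    tip_lengths = tip_lengths or {}
    for i, b in enumerate(model.branches):
        pts = _truncated_polyline(b, tip_lengths[i]) if i in tip_lengths else b.points
        if np.any(np.abs(pts) + b.radius > half):
            raise ValueError(f"branch {i} exits the simulated volume")
        for j in range(len(pts) - 1):
            _paint_capsule(mask, pts[j], pts[j + 1], b.radius, acq)
    return mask


def render_soma(model: CellModel, acq: AcquisitionConfig) -> np.ndarray:
    mask = np.zeros(acq.grid_shape, dtype=bool)
    _paint_capsule(mask, model.soma_center, model.soma_center, model.soma_radius, acq)
    return mask


def _intensity(mask: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    return np.where(mask, acq.intensity_cell, acq.intensity_bg).astype(float)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def simulate_surveillance(
    model: CellModel,
    acq: AcquisitionConfig,
    dynamics: TipDynamics | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Animate process tips and record ground-truth gained/lost voxel counts.

    Each terminal branch oscillates in length with its own speed; the soma and
    internal branches are static, so soma voxels are identical in every frame.
    Truth added/removed counts per transition are exact voxel set differences
    of consecutive noiseless truth masks.
    """
    if acq.n_frames < 2:
        raise ValueError("surveillance needs n_frames >= 2")
    dynamics = dynamics or TipDynamics()
    rng = np.random.default_rng(seed)
    tips = model.terminal_branches()
    base_len = {i: model.branches[i].length for i in tips}
    speeds = {i: max(0.0, rng.normal(dynamics.mean_speed, dynamics.speed_sd)) for i in tips}
    if dynamics.start_sign is None:
        signs = {i: (1.0 if rng.random() < 0.5 else -1.0) for i in tips}
    else:
        signs = {i: float(dynamics.start_sign) for i in tips}
    # tips start at random phases within their oscillation band unless pinned
    if dynamics.start_frac is None:
        cur = {
            i: base_len[i] * (dynamics.min_frac + rng.random() * (dynamics.max_frac - dynamics.min_frac))
            for i in tips
        }
    else:
        cur = {i: base_len[i] * dynamics.start_frac for i in tips}
    dt_min = acq.frame_interval_s / 60.0

    masks = np.zeros((acq.n_frames,) + acq.grid_shape, dtype=bool)
    added = np.zeros(acq.n_frames - 1, dtype=int)
    removed = np.zeros(acq.n_frames - 1, dtype=int)
    for t in range(acq.n_frames):
        masks[t] = render_cell(model, acq, tip_lengths=dict(cur))
        if t > 0:
            added[t - 1] = int(np.count_nonzero(masks[t] & ~masks[t - 1]))
            removed[t - 1] = int(np.count_nonzero(masks[t - 1] & ~masks[t]))
        fac = dynamics.factor_at(t * dt_min)
        for i in tips:
            lo, hi = dynamics.min_frac * base_len[i], dynamics.max_frac * base_len[i]
            nxt = cur[i] + signs[i] * speeds[i] * fac * dt_min
            if nxt > hi:
                nxt = hi - (nxt - hi)
                signs[i] = -signs[i]
            elif nxt < lo:
                nxt = lo + (lo - nxt)
                signs[i] = -signs[i]
            cur[i] = max(nxt, 0.0)

    soma = render_soma(model, acq)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    frames = np.stack([_intensity(m, acq) for m in masks])
    if acq.noise_model is not None:
        frames = np.stack([acq.noise_model.apply(f, noise_rng) for f in frames])
    stack = ImageStack4D(
        data=frames,
        voxel_size_xy=acq.voxel_size_xy,
        voxel_size_z=acq.voxel_size_z,
        frame_interval_s=acq.frame_interval_s,
        metadata={"scenario": "surveillance", "seed": seed},
    )
    truth = CellMaskSeries(
        masks=masks,
        soma=soma,
        voxel_size_xy=acq.voxel_size_xy,
        voxel_size_z=acq.voxel_size_z,
        frame_interval_s=acq.frame_interval_s,
    )
    metrics = {
        "P_true": model.P_true,
        "L_true": model.L_true,
        "V_true_um3": int(masks[0].sum()) * acq.voxel_size_xy**2 * acq.voxel_size_z,
        "added_voxels": added.tolist(),
        "removed_voxels": removed.tolist(),
        "tip_speeds_um_min": {int(k): float(v) for k, v in speeds.items()},
    }
    return SimulationResult(stack=stack, truth_masks=truth, truth_metrics=metrics)


def simulate_chemotaxis(
    center: np.ndarray,
    tau_true: float,
    acq: AcquisitionConfig,
    seed: int = 0,
    *,
    n_rods: int = 36,
    a0_radius: float = 40.0,
    ainf_radius: float = 3.0,
    rod_radius: float = 1.5,
    front_jitter: float = 0.06,
) -> SimulationResult:
    """Simulate microglial process fronts converging on a focal ablation.

    Radial process rods advance toward ``center`` (cell-frame μm, zyx) so that
    the true clear area follows ``A(t) = A_inf + (A0 - A_inf)·exp(-t/τ)`` with
    ``A0 = π·a0_radius²`` and ``A_inf = π·ainf_radius²``.  Per-rod static
    multiplicative jitter makes the front irregular without altering τ.
    ``tau_true`` may be ``inf``: the fronts then stay put.
    """
    if tau_true <= 0:
        raise ValueError("tau_true must be positive")
    center = np.asarray(center, dtype=float)
    shape = acq.grid_shape
    half = (np.array(shape) - 1) / 2.0 * acq.spacings
    if np.any(np.abs(center) > half):
        raise ValueError("ablation center outside the simulated volume")

    rng = np.random.default_rng(seed)
    a0 = math.pi * a0_radius**2
    ainf = math.pi * ainf_radius**2
    times_min = np.arange(acq.n_frames) * acq.frame_interval_s / 60.0
    if math.isinf(tau_true):
        area_truth = np.full(acq.n_frames, a0)
    else:
        area_truth = ainf + (a0 - ainf) * np.exp(-times_min / tau_true)
    r_front = np.sqrt(area_truth / math.pi)

    phis = 2 * math.pi * (np.arange(n_rods) + 0.25 + rng.random(n_rods) * 0.5) / n_rods
    jit = 1.0 + (rng.random(n_rods) - 0.5) * 2 * front_jitter
    dirs = np.stack([np.zeros(n_rods), np.sin(phis), np.cos(phis)], axis=1)
    r_outer = min(a0_radius * 1.4, float(min(half[1], half[2])) - rod_radius - 1.0)

    masks = np.zeros((acq.n_frames,) + shape, dtype=bool)
    for t in range(acq.n_frames):
        m = masks[t]
        for s in range(n_rods):
            # the capsule end-cap extends rod_radius past the segment end, so
            # offset the tip to put the nearest rendered voxel at the front
            front = min(jit[s] * r_front[t], r_outer)
            tip = center + dirs[s] * min(front + rod_radius, r_outer)
            outer = center + dirs[s] * r_outer
            _paint_capsule(m, tip, outer, rod_radius, acq)

    noise_rng = np.random.default_rng(rng.integers(2**31))
    frames = np.stack([_intensity(m, acq) for m in masks])
    if acq.noise_model is not None:
        frames = np.stack([acq.noise_model.apply(f, noise_rng) for f in frames])
    stack = ImageStack4D(
        data=frames,
        voxel_size_xy=acq.voxel_size_xy,
        voxel_size_z=acq.voxel_size_z,
        frame_interval_s=acq.frame_interval_s,
        metadata={"scenario": "chemotaxis", "seed": seed, "center_um_zyx": center.tolist()},
    )
    truth = CellMaskSeries(
        masks=masks,
        soma=np.zeros(shape, dtype=bool),
        voxel_size_xy=acq.voxel_size_xy,
        voxel_size_z=acq.voxel_size_z,
        frame_interval_s=acq.frame_interval_s,
    )
    metrics = {
        "tau_true_min": tau_true,
        "clear_area_truth_um2": area_truth.tolist(),
        "times_min": times_min.tolist(),
        "A0_um2": a0,
        "A_inf_um2": ainf,
    }
    return SimulationResult(stack=stack, truth_masks=truth, truth_metrics=metrics)


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def _shift_frame(frame: np.ndarray, shift: np.ndarray, fill: float) -> np.ndarray:
    """Integer-voxel translation with constant fill (no wrap-around)."""
    out = np.full_like(frame, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for a, s in enumerate(shift):
        s = int(s)
        n = frame.shape[a]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[a] = slice(s, n)
            src[a] = slice(0, n - s)
        else:
            dst[a] = slice(0, n + s)
            src[a] = slice(-s, n)
    out[tuple(dst)] = frame[tuple(src)]
    return out


def inject_artifacts(
    stack: ImageStack4D,
    drift_per_frame: tuple[float, float, float],
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> ImageStack4D:
    """Apply cumulative rigid drift (frame t shifted by round(t·drift) voxels,
    zyx) and then optional Poisson-Gaussian noise.  The injected shifts are
    recorded in ``metadata['true_shifts_voxels']`` for round-trip validation.

    Raises if the cumulative drift would push the volume centre (where the
    simulator places the soma) out of the field of view.
    """
    drift = np.asarray(drift_per_frame, dtype=float)
    n = stack.n_frames
    shape = np.array(stack.data.shape[1:])
    max_shift = np.abs(np.round((n - 1) * drift))
    if np.any(max_shift >= shape / 2):
        raise ValueError("drift would push the soma out of the volume")
    rng = np.random.default_rng(seed)
    fill = float(np.percentile(stack.data[0], 5))
    frames = np.empty_like(stack.data, dtype=float)
    shifts = []
    for t in range(n):
        s = np.round(t * drift).astype(int)
        shifts.append(s.tolist())
        frames[t] = _shift_frame(stack.data[t].astype(float), s, fill)
        if noise_model is not None:
            frames[t] = noise_model.apply(frames[t], rng)
    return stack.copy_with(frames, true_shifts_voxels=shifts)
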