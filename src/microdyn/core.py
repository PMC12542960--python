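"""Core containers for 4D image stacks and per-frame cell masks.

Axis convention throughout the package is ``(t, z, y, x)`` for stacks and
``(z, y, x)`` for single volumes, matching the TZYX order in which time-lapse
two-photon hyperstacks are stored in TIFF.  Physical coordinates are always in
micrometres and are likewise ordered ``(z, y, x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack4D:
    """A single-channel time-lapse volume with its acquisition geometry.

    Parameters
    ----------
    data
        Intensities indexed ``(t, z, y, x)``; must be non-negative.
    voxel_size_xy, voxel_size_z
        Lateral and axial voxel pitch in micrometres.
    frame_interval_s
        Time between consecutive frames in seconds.
    metadata
        Free-form provenance (e.g. ground-truth drift injected by the
        simulator).  Never consumed silently by analysis code.
    """

    data: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float
    frame_interval_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (t, z, y, x) data, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        for name in ("voxel_size_xy", "voxel_size_z", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_xy**2 * self.voxel_size_z

    def copy_with(self, data: np.ndarray, **meta) -> "ImageStack4D":
        md = dict(self.metadata)
        md.update(meta)
        return ImageStack4D(
            data=data,
            voxel_size_xy=self.voxel_size_xy,
            voxel_size_z=self.voxel_size_z,
            frame_interval_s=self.frame_interval_s,
            metadata=md,
        )

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a TZYX TIFF plus a JSON sidecar holding geometry/metadata."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.data), metadata={"axes": "TZYX"})
        sidecar = {
            "voxel_size_xy": self.voxel_size_xy,
            "voxel_size_z": self.voxel_size_z,
            "frame_interval_s": self.frame_interval_s,
            "metadata": _jsonable(self.metadata),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack4D":
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 3:  # single frame
            data = data[None]
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            data=data,
            voxel_size_xy=sidecar["voxel_size_xy"],
            voxel_size_z=sidecar["voxel_size_z"],
            frame_interval_s=sidecar["frame_interval_s"],
            metadata=sidecar.get("metadata", {}),
        )


@dataclass
class CellMaskSeries:
    """Per-frame binary 3D masks of one cell plus its (frame-invariant) soma.

    The soma submask must be contained in the cell mask at every frame; cortical
    microglia keep their soma in place while only the processes remodel, so a
    single soma volume serves the whole series.
    """

    masks: np.ndarray  # (t, z, y, x) bool
    soma: np.ndarray  # (z, y, x) bool
    voxel_size_xy: float
    voxel_size_z: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.soma = np.asarray(self.soma, dtype=bool)
        if self.masks.ndim != 4:
            raise ValueError("masks must be (t, z, y, x)")
        if self.soma.shape != self.masks.shape[1:]:
            raise ValueError("soma shape must match a single frame")
        bad = [t for t in range(self.masks.shape[0]) if np.any(self.soma & ~self.masks[t])]
        if bad:
            raise ValueError(f"soma not contained in cell mask at frames {bad}")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def pixel_area_um2(self) -> float:
        return self.voxel_size_xy**2

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_xy**2 * self.voxel_size_z

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 60.0

    def projection(self, t: int) -> np.ndarray:
        """Maximum-z projection of frame ``t`` (binary)."""
        return self.masks[t].any(axis=0)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.masks.astype(np.uint8) * 255, metadata={"axes": "TZYX"})
        tifffile.imwrite(_soma_path(path), self.soma.astype(np.uint8) * 255, metadata={"axes": "ZYX"})
        sidecar = {
            "voxel_size_xy": self.voxel_size_xy,
            "voxel_size_z": self.voxel_size_z,
            "frame_interval_s": self.frame_interval_s,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CellMaskSeries":
        path = Path(path)
        masks = tifffile.imread(path) > 0
        if masks.ndim == 3:
            masks = masks[None]
        soma = tifffile.imread(_soma_path(path)) > 0
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(masks=masks, soma=soma, **sidecar)


def _soma_path(path: Path) -> Path:
    return path.with_name(path.stem + "_soma" + path.suffix)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
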