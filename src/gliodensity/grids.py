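"""Voxel grid geometry shared by every volume in the pipeline.

World convention: the center of voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * voxel_size`` (millimetres).  All distances,
boundary coordinates and surface metrics are expressed in this world
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer label codes used in every tissue-label volume.
LABELS = {
    "background": 0,
    "csf": 1,
    "gray": 2,
    "white": 3,
    "core": 4,
    "necrosis": 5,
}

BRAIN_LABELS = (LABELS["gray"], LABELS["white"], LABELS["core"], LABELS["necrosis"])


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned regular voxel grid.

    Parameters
    ----------
    shape
        Number of voxels per axis.
    voxel_size
        Voxel edge length per axis, in mm.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = self.voxel_size
        if np.isscalar(vs):
            vs = (float(vs),) * 3
        else:
            vs = tuple(float(v) for v in vs)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be positive on every axis, got {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.voxel_size, dtype=float)

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the grid (mm)."""
        return np.asarray(self.shape, dtype=float) * self.spacing

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for (N, 3) integer indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * self.spacing[None, :] + np.asarray(self.origin)[None, :]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))


@dataclass
class TissueLabelVolume:
    """3D voxel grid of tissue classes (see :data:`LABELS`)."""

    grid: VoxelGrid
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid shape")
        bad = ~np.isin(self.labels, list(LABELS.values()))
        if bad.any():
            raise ValueError(f"unknown label codes present: {np.unique(self.labels[bad])}")

    def mask(self, *names: str) -> np.ndarray:
        codes = [LABELS[n] for n in names]
        return np.isin(self.labels, codes)

    @property
    def brain_mask(self) -> np.ndarray:
        return np.isin(self.labels, BRAIN_LABELS)

    @property
    def white_mask(self) -> np.ndarray:
        return self.labels == LABELS["white"]

    @property
    def core_mask(self) -> np.ndarray:
        """Tumor core including its necrotic center."""
        return np.isin(self.labels, (LABELS["core"], LABELS["necrosis"]))


@dataclass
class ScalarVolume:
    """3D scalar field on a voxel grid (distance in mm, density in cell/mm^3, ...)."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid shape")
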