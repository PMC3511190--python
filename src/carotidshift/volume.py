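"""Voxel containers: scalar volumes and binary masks on a physical grid.

Arrays are indexed ``(i, j, k)`` along the physical ``(x, y, z)`` axes, with
``world = origin + index * spacing`` (axis-aligned grids only, which is all
the phantom and pipeline need).  I/O goes through SimpleITK so volumes can be
written as MetaImage or NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk


class GridMismatchError(ValueError):
    """Two grids that must share geometry do not."""


@dataclass
class VoxelVolume:
    """3D scalar grid with physical spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, other: "VoxelVolume") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def require_same_grid(self, other: "VoxelVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}")

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # -- I/O --------------------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # sitk expects (z, y, x) array order
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    def write(self, path) -> None:
        sitk.WriteImage(self.to_sitk(), str(Path(path)))

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VoxelVolume":
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(data=data, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))

    @classmethod
    def read(cls, path) -> "VoxelVolume":
        return cls.from_sitk(sitk.ReadImage(str(Path(path))))


@dataclass
class BinaryMask(VoxelVolume):
    """Boolean voxel mask with a segment label, sharing VoxelVolume geometry."""

    label: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @classmethod
    def from_volume(cls, volume: VoxelVolume, data: np.ndarray, label: str = "") -> "BinaryMask":
        return cls(data=data, spacing=volume.spacing, origin=volume.origin, label=label)

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume_mm3()

    def centroid(self) -> np.ndarray:
        """Voxel-count centroid in world mm; error on an empty mask."""
        if not self.data.any():
            raise ValueError(f"mask '{self.label}' is empty; centroid undefined")
        idx = np.argwhere(self.data)
        return self.index_to_world(idx.mean(axis=0))

    def write(self, path) -> None:
        VoxelVolume(self.data.astype(np.uint8), self.spacing, self.origin).write(path)
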