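"""Threshold segmentation, Boolean vessel subtraction, region growing,
surface extraction and the Dice overlap quality gate.

The workflow mirrors paired CTA / plain-CT processing: bone is thresholded
from the non-contrast volume, the contrast volume thresholded at a lower
window contains bone *and* vessel, and the vessel is their Boolean
difference.  Region growing keeps the 26-connected component around a seed,
discarding disconnected debris.  Segmentation quality between two
co-registered acquisitions is gated on the Dice coefficient
``s = 2|A n B| / (|A| + |B|)`` with the conventional s > 0.95 pass mark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .geometry import RigidTransform
from .volume import BinaryMask, VoxelVolume

DICE_PASS_THRESHOLD = 0.95

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentModel:
    """A named rigid body: closed triangulated surface and/or voxel mask."""

    name: str
    mesh: Optional[trimesh.Trimesh] = None
    mask: Optional[BinaryMask] = None

    def transformed(self, transform: RigidTransform) -> "SegmentModel":
        """Rigidly move the surface (the mask is not resampled here; use
        :func:`resample_mask` when a moved voxel mask is needed)."""
        mesh = None
        if self.mesh is not None:
            mesh = self.mesh.copy()
            mesh.vertices = transform.apply(mesh.vertices)
        return SegmentModel(name=self.name, mesh=mesh, mask=self.mask)


@dataclass(frozen=True)
class DiceReport:
    """Dice similarity between two co-registered masks, with volumes."""

    s: float
    volume_a: float
    volume_b: float
    passed: bool

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"dice coefficient out of [0, 1]: {self.s}")


def threshold_mask(volume: VoxelVolume, lower: float, upper: float,
                   label: str = "") -> BinaryMask:
    """Voxels with ``lower <= intensity <= upper``.

    An empty result is returned with a warning rather than an error — the
    caller decides whether an empty window is fatal.
    """
    if lower >= upper:
        raise SegmentationError(f"threshold window is empty: [{lower}, {upper}]")
    data = (volume.data >= lower) & (volume.data <= upper)
    if not data.any():
        warnings.warn(f"threshold window [{lower}, {upper}] selected no voxels",
                      stacklevel=2)
    return BinaryMask.from_volume(volume, data, label=label)


def subtract_masks(inclusive: BinaryMask, bones: BinaryMask,
                   label: str = "") -> BinaryMask:
    """``inclusive AND NOT bones`` — e.g. (bone+vessel) minus bone = vessel."""
    inclusive.require_same_grid(bones)
    return BinaryMask.from_volume(inclusive, inclusive.data & ~bones.data, label=label)


def region_grow(mask: BinaryMask, seed_point, label: str = "") -> BinaryMask:
    """Keep the 26-connected component containing ``seed_point`` (mm)."""
    idx = np.round(mask.world_to_index(seed_point)).astype(int)
    at = tuple(int(i) for i in idx)
    if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)):
        raise SegmentationError(f"seed {tuple(seed_point)} maps outside the grid at voxel {at}")
    if not mask.data[at]:
        raise SegmentationError(f"seed voxel {at} is not set in the mask")
    labels, _ = ndimage.label(mask.data, structure=_CONN26)
    keep = labels == labels[tuple(idx)]
    return BinaryMask.from_volume(mask, keep, label=label or mask.label)


def extract_surface(mask: BinaryMask, name: str = "",
                    smooth_sigma_vox: float = 0.0) -> SegmentModel:
    """Closed triangulated surface at the 0.5 iso-level of the mask.

    Vertices are in physical mm coordinates.  The marching-cubes run is
    restricted to the mask's bounding box (padded so the surface closes).

    With ``smooth_sigma_vox > 0`` the binary field is Gaussian-smoothed
    (sigma in voxels) before iso-surfacing.  This anti-aliases the
    lattice-aligned terracing of binary marching cubes — which otherwise
    biases surface registration between two rasterizations of the same
    body in different poses — at the cost of a slight curvature-dependent
    volume shrinkage, so leave it off when enclosed volume matters.
    """
    if not mask.data.any():
        raise SegmentationError(f"cannot extract a surface from empty mask '{mask.label}'")
    idx = np.argwhere(mask.data)
    pad = 2 + int(np.ceil(3 * smooth_sigma_vox))
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sub = mask.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float32)
    sub = np.pad(sub, 1)
    if smooth_sigma_vox > 0:
        sub = ndimage.gaussian_filter(sub, sigma=smooth_sigma_vox)
    spacing = np.asarray(mask.spacing)
    verts, faces, _, _ = marching_cubes(sub, level=0.5, spacing=tuple(spacing))
    verts = verts + (lo - 1) * spacing + np.asarray(mask.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return SegmentModel(name=name or mask.label, mesh=mesh, mask=mask)


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> DiceReport:
    """Dice overlap of two masks on the same grid.

    The caller is responsible for resampling an ICP-aligned moving mask onto
    the reference grid first (see :func:`resample_mask`).
    """
    mask_a.require_same_grid(mask_b)
    na, nb = mask_a.count(), mask_b.count()
    if na == 0 and nb == 0:
        raise SegmentationError("dice undefined: both masks are empty")
    inter = int((mask_a.data & mask_b.data).sum())
    s = 2.0 * inter / (na + nb)
    return DiceReport(s=s, volume_a=mask_a.volume_mm3(), volume_b=mask_b.volume_mm3(),
                      passed=s > DICE_PASS_THRESHOLD)


def resample_mask(mask: BinaryMask, transform: RigidTransform,
                  reference: VoxelVolume) -> BinaryMask:
    """Nearest-neighbour resample of a rigidly moved mask onto a reference grid.

    ``transform`` maps the mask's world coordinates into the reference's
    world coordinates (e.g. the composed global + per-segment alignment).
    """
    s_in = np.asarray(mask.spacing)
    s_out = np.asarray(reference.spacing)
    inv = transform.inverse()
    # output index i -> world y = o_out + s_out*i -> x = inv(y) -> input index
    a = (inv.rotation * s_out[np.newaxis, :]) / s_in[:, np.newaxis]
    b = (inv.rotation @ np.asarray(reference.origin) + inv.translation
         - np.asarray(mask.origin)) / s_in
    out = ndimage.affine_transform(mask.data.astype(np.uint8), a, offset=b,
                                   output_shape=reference.shape, order=0,
                                   mode="constant", cval=0)
    return BinaryMask.from_volume(reference, out.astype(bool), label=mask.label)
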