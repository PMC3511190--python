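"""Anatomically standardized coordinate system and displacement parameters.

Scanner coordinates differ between acquisitions and patients, so per-segment
displacements are mapped into a standardized coordinate system (SCS) built
from the maxillofacial (fiducial) segment: origin at its center of gravity,
axes along its principal axes of inertia, signed so x/y/z point roughly
posterior/left/superior.  A displacement ``T_l`` measured in the scanner
frame (PCS) maps into the SCS by conjugation::

    T_m = T_PCS->SCS . T_l . T_PCS->SCS^-1

and is then decomposed into three translation components (mm) and three
Euler angles (degrees, extrinsic x->y->z: ``R = Rz(gamma) Ry(beta) Rx(alpha)``)
about axes through the segment's reference-acquisition centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .segmentation import SegmentModel


class FrameError(ValueError):
    pass


@dataclass(frozen=True)
class StandardFrame:
    """Standardized frame: origin (mm) and row-stacked orthonormal axes.

    ``axes[i]`` is the world-frame direction of SCS axis i, so SCS
    coordinates of a world point p are ``axes @ (p - origin)``.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise FrameError("frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise FrameError("frame axes are left-handed")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def as_transform(self) -> RigidTransform:
        """T_PCS->SCS as a rigid transform."""
        return RigidTransform.from_rotation_translation(self.axes, -self.axes @ self.origin)

    def to_scs(self, points) -> np.ndarray:
        return self.as_transform.apply(points)


@dataclass
class DisplacementRecord:
    """Six displacement parameters of one segment in one frame.

    Translations in mm, angles in degrees on ``(-180, 180]``.  Bifurcation
    records carry positions only (angles are ``None``).
    """

    segment: str
    frame: str  # "PCS" | "SCS"
    dx: float
    dy: float
    dz: float
    dalpha: Optional[float] = None
    dbeta: Optional[float] = None
    dgamma: Optional[float] = None

    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation()))


def center_of_gravity(model: SegmentModel) -> np.ndarray:
    """Centroid of the uniform-density solid (mm).

    Prefers the watertight surface (exact polyhedral integral); falls back
    to voxel summation over the mask.  The two agree to within half a voxel
    on well-resolved segments.
    """
    if model.mesh is not None:
        if not model.mesh.is_watertight:
            if model.mask is not None:
                return model.mask.centroid()
            raise FrameError(f"surface of '{model.name}' is not watertight and no mask is available")
        return np.asarray(model.mesh.center_mass, dtype=float)
    if model.mask is not None:
        return model.mask.centroid()
    raise FrameError(f"segment '{model.name}' has neither surface nor mask")


def _inertia_tensor(model: SegmentModel) -> tuple:
    """(tensor about centroid, centroid) of the uniform-density solid."""
    c = center_of_gravity(model)
    if model.mesh is not None and model.mesh.is_watertight:
        return np.asarray(model.mesh.moment_inertia, dtype=float), c
    mask = model.mask
    pts = mask.index_to_world(np.argwhere(mask.data)) - c
    r2 = (pts ** 2).sum(axis=1)
    tensor = np.eye(3) * r2.sum() - pts.T @ pts
    return tensor, c


def inertia_axes(model: SegmentModel, hints) -> StandardFrame:
    """Standardized frame from the principal axes of inertia.

    ``hints`` are three unit vectors (approximate posterior, left, superior
    directions); each principal axis is assigned to the hint it aligns with
    best (one-to-one) and signed to point along it.  If the resulting triad
    is left-handed the axis with the weakest hint alignment is flipped.
    """
    hints = np.asarray(hints, dtype=float)
    if hints.shape != (3, 3):
        raise FrameError("expected three 3D hint vectors")
    hints = hints / np.linalg.norm(hints, axis=1, keepdims=True)
    tensor, c = _inertia_tensor(model)
    evals, evecs = np.linalg.eigh(tensor)
    gaps = np.abs(np.diff(evals)) / max(abs(evals).max(), 1e-30)
    if np.any(gaps < 1e-6):
        raise FrameError("principal moments are degenerate; the shape is "
                         "(near-)rotationally symmetric and its axes are not unique")
    dots = hints @ evecs  # dots[axis, k] = hint_axis . evec_k
    axis_idx, vec_idx = linear_sum_assignment(-np.abs(dots))
    axes = np.zeros((3, 3))
    strengths = np.zeros(3)
    for a, k in zip(axis_idx, vec_idx):
        v = evecs[:, k]
        if dots[a, k] < 0:
            v = -v
        axes[a] = v
        strengths[a] = abs(dots[a, k])
    if np.linalg.det(axes) < 0:
        axes[int(np.argmin(strengths))] *= -1
    return StandardFrame(origin=c, axes=axes)


def to_standard(t_l: RigidTransform, frame: StandardFrame) -> RigidTransform:
    """Conjugate a scanner-frame displacement into the standardized frame:
    ``T_m = F T_l F^-1``.  The rotation angle is preserved."""
    f = frame.as_transform
    return f @ t_l @ f.inverse()


def euler_decompose(t: RigidTransform, pivot, segment: str = "",
                    frame: str = "PCS") -> DisplacementRecord:
    """Six displacement parameters of ``t`` about axes through ``pivot``.

    Translation components are the displacement of the pivot (the segment's
    reference centroid); rotation is factored extrinsically as
    ``R = Rz(gamma) Ry(beta) Rx(alpha)`` (x applied first, order
    alpha -> beta -> gamma).  ``|beta| = 90 deg`` is gimbal-locked and
    rejected.
    """
    pivot = np.asarray(pivot, dtype=float)
    d = t.apply(pivot) - pivot
    # in the R = Rz Ry Rx factorization, R[2,0] = -sin(beta)
    beta_deg = float(np.rad2deg(np.arcsin(np.clip(-t.rotation[2, 0], -1.0, 1.0))))
    if 90.0 - abs(beta_deg) < 1e-6:
        raise FrameError(f"gimbal lock: beta = {beta_deg:.6f} deg")
    rot = Rotation.from_matrix(t.rotation)
    alpha, beta, gamma = rot.as_euler("xyz", degrees=True)
    return DisplacementRecord(segment=segment, frame=frame,
                              dx=float(d[0]), dy=float(d[1]), dz=float(d[2]),
                              dalpha=float(alpha), dbeta=float(beta), dgamma=float(gamma))


def euler_recompose(record: DisplacementRecord, pivot) -> RigidTransform:
    """Inverse of :func:`euler_decompose` (round-trip identity)."""
    return RigidTransform.from_euler_xyz(record.dalpha, record.dbeta, record.dgamma,
                                         translation=record.translation(), pivot=pivot)
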