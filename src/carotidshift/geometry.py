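"""Rigid transforms in homogeneous coordinates.

Everything downstream (registration, frame standardization, phantom motion)
speaks in terms of :class:`RigidTransform`: a proper rigid motion
``x -> R x + t`` stored as a 4x4 homogeneous matrix.  Rotations are required
to be proper (``det R = +1``) and orthonormal to tight tolerance; transforms
that fail those checks are rejected at construction so invalid matrices
cannot propagate silently through a pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


class RigidityError(ValueError):
    """Raised when a matrix is not a proper rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` (mm).

    Parameters
    ----------
    matrix
        4x4 homogeneous matrix with orthonormal rotation block, unit
        determinant and last row ``(0, 0, 0, 1)``.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise RigidityError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
            raise RigidityError("last row must be (0, 0, 0, 1)")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise RigidityError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise RigidityError("rotation block is a reflection (det < 0)")
        object.__setattr__(self, "matrix", m)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), translation)

    @classmethod
    def from_euler_xyz(cls, alpha_deg: float, beta_deg: float, gamma_deg: float,
                       translation=(0.0, 0.0, 0.0), pivot=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Extrinsic x->y->z rotation (``R = Rz(gamma) Ry(beta) Rx(alpha)``)
        about ``pivot``, then translation of the pivot by ``translation``."""
        r = Rotation.from_euler("xyz", [alpha_deg, beta_deg, gamma_deg], degrees=True).as_matrix()
        pivot = np.asarray(pivot, dtype=float)
        t = np.asarray(translation, dtype=float) + pivot - r @ pivot
        return cls.from_rotation_translation(r, t)

    @classmethod
    def rotation_about(cls, axis, angle_deg: float, pivot=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation of ``angle_deg`` about the given axis through ``pivot``."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        r = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        pivot = np.asarray(pivot, dtype=float)
        return cls.from_rotation_translation(r, pivot - r @ pivot)

    # -- accessors --------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    # -- algebra ----------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(_reorthonormalize(self.matrix @ other.matrix))

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` array (or a single 3-vector) of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.asarray(vectors, dtype=float)
        single = v.ndim == 1
        out = np.atleast_2d(v) @ self.rotation.T
        return out[0] if single else out

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


def _reorthonormalize(m: np.ndarray) -> np.ndarray:
    """Snap the rotation block back onto SO(3) after composition round-off."""
    u, _, vt = np.linalg.svd(m[:3, :3])
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    out = np.eye(4)
    out[:3, :3] = r
    out[:3, 3] = m[:3, 3]
    return out


def rotation_between(a: RigidTransform, b: RigidTransform) -> float:
    """Angle (degrees) of the relative rotation between two transforms."""
    return (a.inverse() @ b).rotation_angle_deg()


def translation_between(a: RigidTransform, b: RigidTransform) -> float:
    """Norm (mm) of the difference of the translation parts."""
    return float(np.linalg.norm(a.translation - b.translation))
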