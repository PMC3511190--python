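"""Rigid surface alignment: Kabsch least squares, ICP, the global fiducial
superimposition and per-segment displacement matrices.

The two acquisitions are first brought into a common frame by superimposing
the maxillofacial (fiducial) surfaces with ICP, yielding the global
transform ``T``; each remaining segment of the aligned second acquisition
is then superimposed onto its first-acquisition counterpart, yielding the
per-segment matrices ``T_C1 .. T_C4, T_mandible, T_CA`` whose inverses are
the residual per-segment displacements.

ICP correspondence is vertex-to-nearest-point on the target surface
(candidate faces from a face-centroid k-d tree, exact point-triangle
projection among candidates), with optional uniform vertex subsampling and
optional residual trimming.  Initialization is the identity: the paired
acquisitions share a scanner frame and the phantom is generated
near-aligned; a principal-axes pre-alignment is available for large
motions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform
from .segmentation import SegmentModel


class RegistrationError(ValueError):
    pass


@dataclass(frozen=True)
class IcpSettings:
    max_iterations: int = 100
    convergence_tol: float = 1e-4  # mm RMS change
    subsample: int = 2000          # source vertices used (0 = all)
    outlier_trim_fraction: float = 0.0
    candidate_faces: int = 8
    prealign_axes: bool = False
    #: after point-to-point convergence, polish with a symmetric
    #: point-to-plane Gauss-Newton stage: residuals along surface normals in
    #: both directions largely cancel the voxelization-ripple bias that
    #: limits point-to-point alignment of two rasterized surfaces
    refine_point_to_plane: bool = True
    refine_subsample: int = 4000

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.outlier_trim_fraction < 0.5:
            raise ValueError("outlier_trim_fraction must be in [0, 0.5)")


@dataclass
class IcpResult:
    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool


def kabsch(source_points, target_points) -> RigidTransform:
    """Least-squares rigid transform mapping source onto target.

    Minimizes ``sum ||T p_i - q_i||^2`` over proper rigid motions (the SVD
    determinant correction forbids reflections).  Requires >= 3
    non-collinear correspondences.
    """
    p = np.asarray(source_points, float)
    q = np.asarray(target_points, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise RegistrationError("source and target must be matching (n, 3) arrays")
    if len(p) < 3:
        raise RegistrationError("need at least 3 correspondences")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    if np.linalg.matrix_rank(np.cov((p - pc).T)) < 2:
        raise RegistrationError("correspondences are collinear/degenerate (rank < 2)")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - r @ pc
    return RigidTransform.from_rotation_translation(r, t)


class _SurfaceLocator:
    """Nearest point (and its face normal) on a triangulated surface via
    candidate faces from a face-centroid k-d tree."""

    def __init__(self, mesh: trimesh.Trimesh, k: int):
        self.triangles = mesh.triangles.copy()
        self.normals = mesh.face_normals.copy()
        self.tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(self.triangles))

    def _best(self, points: np.ndarray):
        _, cand = self.tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        tri = self.triangles[cand.ravel()]
        rep = np.repeat(points, k, axis=0)
        proj = trimesh.triangles.closest_point(tri, rep)
        d2 = ((proj - rep) ** 2).sum(axis=1).reshape(n, k)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        return proj.reshape(n, k, 3)[rows, best], cand[rows, best]

    def closest(self, points: np.ndarray) -> np.ndarray:
        return self._best(points)[0]

    def closest_with_normals(self, points: np.ndarray):
        proj, faces = self._best(points)
        return proj, self.normals[faces]


def _principal_prealign(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Coarse alignment of vertex clouds by centroid + covariance axes."""
    def axes(x):
        c = x.mean(axis=0)
        w, v = np.linalg.eigh(np.cov((x - c).T))
        if np.linalg.det(v) < 0:
            v[:, 0] *= -1
        return c, v
    cs, vs = axes(src)
    ct, vt = axes(tgt)
    r = vt @ vs.T
    if np.linalg.det(r) < 0:
        vt[:, 0] *= -1
        r = vt @ vs.T
    return RigidTransform.from_rotation_translation(r, ct - r @ cs)


def icp(source: SegmentModel, target: SegmentModel,
        settings: Optional[IcpSettings] = None) -> IcpResult:
    """Iterative closest point alignment of two surfaces.

    Returns the rigid transform mapping ``source`` onto ``target`` plus the
    final RMS point-to-surface distance; if the RMS change never drops below
    ``convergence_tol`` the result is flagged non-converged but still
    returned.
    """
    settings = settings or IcpSettings()
    if source.mesh is None or target.mesh is None or len(source.mesh.vertices) == 0:
        raise RegistrationError("both segments need non-empty surfaces")
    pts = np.asarray(source.mesh.vertices, float)
    if settings.subsample and len(pts) > settings.subsample:
        stride = int(np.ceil(len(pts) / settings.subsample))
        pts = pts[::stride]  # uniform, lowest-index first: deterministic
    locator = _SurfaceLocator(target.mesh, settings.candidate_faces)

    transform = (_principal_prealign(pts, np.asarray(target.mesh.vertices, float))
                 if settings.prealign_axes else RigidTransform.identity())
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, settings.max_iterations + 1):
        moved = transform.apply(pts)
        matched = locator.closest(moved)
        resid = np.linalg.norm(moved - matched, axis=1)
        if settings.outlier_trim_fraction > 0:
            keep = resid.argsort()[: int(np.ceil(len(resid) * (1 - settings.outlier_trim_fraction)))]
        else:
            keep = slice(None)
        step = kabsch(moved[keep], matched[keep])
        transform = step @ transform
        moved = transform.apply(pts)
        rms = float(np.sqrt(((moved - locator.closest(moved)) ** 2).sum(axis=1).mean()))
        if abs(prev_rms - rms) < settings.convergence_tol:
            converged = True
            break
        prev_rms = rms
    if settings.refine_point_to_plane:
        transform = _symmetric_point_to_plane(source.mesh, target.mesh, transform,
                                              locator, settings)
        moved = transform.apply(pts)
        rms = float(np.sqrt(((moved - locator.closest(moved)) ** 2).sum(axis=1).mean()))
    return IcpResult(transform=transform, rms=rms, iterations=it, converged=converged)


def _subsample(vertices: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(vertices, float)
    if n and len(v) > n:
        v = v[::int(np.ceil(len(v) / n))]
    return v


def _symmetric_point_to_plane(src_mesh, tgt_mesh, transform, tgt_locator,
                              settings, iterations: int = 40, tol: float = 1e-10):
    """Gauss-Newton polish of a near-converged alignment, minimizing
    point-to-plane residuals with correspondences in both directions."""
    sp = _subsample(src_mesh.vertices, settings.refine_subsample)
    tp = _subsample(tgt_mesh.vertices, settings.refine_subsample)
    src_locator = _SurfaceLocator(src_mesh, settings.candidate_faces)
    prev = np.inf
    for _ in range(iterations):
        p = transform.apply(sp)
        q, nq = tgt_locator.closest_with_normals(p)
        back = transform.inverse().apply(tp)
        q2, n2 = src_locator.closest_with_normals(back)
        p_all = np.vstack([p, transform.apply(q2)])
        q_all = np.vstack([q, tp])
        n_all = np.vstack([nq, transform.apply_vectors(n2)])
        b = -((p_all - q_all) * n_all).sum(axis=1)
        a = np.hstack([np.cross(p_all, n_all), n_all])
        x, *_ = np.linalg.lstsq(a, b, rcond=None)
        step = RigidTransform.from_rotation_translation(
            Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])
        transform = step @ transform
        rms = float(np.sqrt((((p_all - q_all) * n_all).sum(axis=1) ** 2).mean()))
        if abs(prev - rms) < tol:
            break
        prev = rms
    return transform


def global_align(dataset2_segments: dict, dataset1_segments: dict,
                 settings: Optional[IcpSettings] = None) -> IcpResult:
    """Fiducial superimposition ``T``: maxillofacial of data set 2 onto that
    of data set 1.  ``T`` is applied to every model of data set 2 before any
    per-segment analysis."""
    for name, segs in (("data set 2", dataset2_segments), ("data set 1", dataset1_segments)):
        if "maxillofacial" not in segs:
            raise RegistrationError(f"{name} has no maxillofacial segment")
    return icp(dataset2_segments["maxillofacial"], dataset1_segments["maxillofacial"], settings)


def per_segment_transform(segment_name: str, dataset2_aligned: dict, dataset1: dict,
                          settings: Optional[IcpSettings] = None) -> IcpResult:
    """Superimposition of one globally aligned data-set-2 segment onto its
    data-set-1 counterpart (``T_C1 .. T_CA``).  Its inverse is the residual
    forward displacement of the segment."""
    for name, segs in (("data set 2", dataset2_aligned), ("data set 1", dataset1)):
        if segment_name not in segs:
            raise RegistrationError(f"segment '{segment_name}' missing from {name}")
    return icp(dataset2_aligned[segment_name], dataset1[segment_name], settings)


def centroid_shift(model: SegmentModel, t_seg: RigidTransform) -> float:
    """``||T c - c||`` for the segment's data-set-1 center of gravity c.

    Invariant to the coordinate frame (rigid frames preserve norms).
    """
    from .frames import center_of_gravity
    c = center_of_gravity(model)
    return float(np.linalg.norm(t_seg.apply(c) - c))
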