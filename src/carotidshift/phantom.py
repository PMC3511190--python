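"""Digital neck phantom: paired pre/post scenes with known ground truth.

The phantom emulates the anatomy relevant to carotid catheter navigation: a
maxillofacial (skull) fiducial segment, the C1-C4 cervical vertebrae, the
mandible, and a contrast-enhanced carotid tree (CCA splitting at vA into
ICA and ECA; the ECA giving off the lingual, facial, occipital and
maxillary arteries at vB-vE and continuing as the STA).  Each bone is an
asymmetric union of ellipsoids and boxes, so its principal inertia axes are
unique and stable; the vessel is a union of capsules along branch
polylines.

A "post" scene is produced by moving each bone rigidly and deforming the
vessel centerline with a normalized Gaussian-weighted blend of the bone
motions::

    d(p) = sum_s w_s(p) (T_s p - p) / sum_s w_s(p),
    w_s(p) = exp(-||p - c_s||^2 / sigma^2)

with c_s the pre-pose bone centroids.  This instantiates the
rigid-surroundings assumption (bones drive the artery) while keeping the
bifurcation displacements an exactly evaluable function of the injected
motions, so every downstream stage can be validated against analytic truth.

Scenes voxelize to a contrast (bone + vessel) and a non-contrast
(bone only) volume on a CT-like grid (default 0.43 x 0.43 mm pixels,
0.5 mm slice interval), with optional additive Gaussian intensity noise.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .centerline import BIFURCATION_LABELS, CenterlineTree
from .geometry import RigidTransform
from .segmentation import SegmentModel, extract_surface
from .volume import BinaryMask, VoxelVolume

BONE_NAMES = ("maxillofacial", "C1", "C2", "C3", "C4", "mandible")
BRANCH_NAMES = ("CCA", "ICA", "ECA", "STA", "LA", "FA", "OA", "MA")


class PhantomConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# implicit solids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple
    semiaxes: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = (points - np.asarray(self.center)) / np.asarray(self.semiaxes)
        return (q ** 2).sum(axis=-1) <= 1.0

    def bounds(self):
        c, s = np.asarray(self.center), np.asarray(self.semiaxes)
        return c - s, c + s


@dataclass(frozen=True)
class Box:
    center: tuple
    half: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = np.abs(points - np.asarray(self.center)) <= np.asarray(self.half)
        return q.all(axis=-1)

    def bounds(self):
        c, h = np.asarray(self.center), np.asarray(self.half)
        return c - h, c + h


class CompositeSolid:
    """Union of primitives, optionally carried through a rigid pose."""

    def __init__(self, primitives, pose: Optional[RigidTransform] = None):
        self.primitives = list(primitives)
        self.pose = pose or RigidTransform.identity()

    def posed(self, pose: RigidTransform) -> "CompositeSolid":
        return CompositeSolid(self.primitives, pose @ self.pose)

    def bounds(self):
        los, his = zip(*(p.bounds() for p in self.primitives))
        lo, hi = np.min(los, axis=0), np.max(his, axis=0)
        corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                            for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
        moved = self.pose.apply(corners)
        return moved.min(axis=0), moved.max(axis=0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        local = self.pose.inverse().apply(points)
        out = np.zeros(len(local), dtype=bool)
        for prim in self.primitives:
            out |= prim.contains(local)
        return out

    def rasterize(self, shape, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Boolean occupancy on an axis-aligned grid (evaluated only inside
        the solid's bounding box for speed)."""
        spacing = np.asarray(spacing, float)
        origin = np.asarray(origin, float)
        lo, hi = self.bounds()
        i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 2, shape)
        out = np.zeros(shape, dtype=bool)
        if np.any(i0 >= i1):
            return out
        grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(i0, i1)], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        pts = idx * spacing + origin
        hits = self.contains(pts)
        sub = hits.reshape([b - a for a, b in zip(i0, i1)])
        out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = sub
        return out


def _spec_to_solid(spec) -> CompositeSolid:
    prims = []
    for kind, a, b in spec:
        if kind == "ellipsoid":
            prims.append(Ellipsoid(tuple(a), tuple(b)))
        elif kind == "box":
            prims.append(Box(tuple(a), tuple(b)))
        else:
            raise PhantomConfigurationError(f"unknown primitive kind '{kind}'")
    return CompositeSolid(prims)


# ---------------------------------------------------------------------------
# default anatomy (mm; x posterior, y left, z superior)
# ---------------------------------------------------------------------------

# Segments are unions of smooth rounded primitives: flat box faces produce
# terraced iso-surfaces after voxelization that bias surface registration,
# while ellipsoids stay smooth at any pose.  Each segment carries off-axis
# lumps so its principal inertia moments are pairwise distinct and its
# surface constrains all six rigid degrees of freedom.
DEFAULT_SEGMENT_SHAPES = {
    "maxillofacial": (
        ("ellipsoid", (36, 34, 94), (20, 15, 12)),
        ("ellipsoid", (24, 30, 88), (8, 10, 6)),
        ("ellipsoid", (46, 42, 100), (7, 5, 6)),
        ("ellipsoid", (30, 26, 102), (4, 4, 3.5)),
    ),
    "mandible": (
        ("ellipsoid", (16, 34, 74), (6.5, 11, 4.5)),
        ("ellipsoid", (22, 25, 76), (3.5, 3, 4)),
        ("ellipsoid", (22, 43, 76), (3.5, 3, 4)),
        ("ellipsoid", (11, 39, 71), (3, 3.5, 3)),
    ),
    # vertebrae: ellipsoid body + posterior (spinous) process + one
    # transverse lump and one small anterior lump, sides alternating down
    # the column; bodies are 14 mm apart so inter-vertebral clearance stays
    # ~3 mm under sampled motions
    "C1": (
        ("ellipsoid", (46, 34, 75), (13, 9, 5.5)),
        ("ellipsoid", (57, 34, 75), (7, 3.2, 3.2)),
        ("ellipsoid", (50, 43, 75), (4, 4, 4)),
        ("ellipsoid", (40, 26, 77), (4, 3, 3)),
    ),
    "C2": (
        ("ellipsoid", (46, 34, 61), (13, 9, 5.5)),
        ("ellipsoid", (57, 34, 61), (7, 3.2, 3.2)),
        ("ellipsoid", (50, 25, 61), (4, 4, 4)),
        ("ellipsoid", (40, 42, 59), (4, 3, 3)),
    ),
    "C3": (
        ("ellipsoid", (46, 34, 47), (13, 9, 5.5)),
        ("ellipsoid", (57, 34, 47), (7, 3.2, 3.2)),
        ("ellipsoid", (42, 43, 47), (4, 4, 4)),
        ("ellipsoid", (52, 26, 49), (4, 3, 3)),
    ),
    "C4": (
        ("ellipsoid", (46, 34, 33), (13, 9, 5.5)),
        ("ellipsoid", (57, 34, 33), (7, 3.2, 3.2)),
        ("ellipsoid", (42, 25, 33), (4, 4, 4)),
        ("ellipsoid", (52, 42, 31), (4, 3, 3)),
    ),
}

# carotid tree: (branch, node_u, node_v, control polyline)
DEFAULT_BRANCH_EDGES = (
    ("CCA", "root", "vA", ((40, 53, 14), (40, 53.5, 32), (40, 54, 46))),
    ("ICA", "vA", "ica_end", ((40, 54, 46), (43, 55, 60), (45, 56, 78), (44, 56, 96))),
    ("ECA", "vA", "vB", ((40, 54, 46), (36, 55, 52), (34, 55, 56))),
    ("ECA", "vB", "vC", ((34, 55, 56), (33, 55.5, 59.5), (32, 56, 63))),
    ("ECA", "vC", "vD", ((32, 56, 63), (31.5, 56, 67), (31, 56, 71))),
    ("ECA", "vD", "vE", ((31, 56, 71), (30.5, 56, 75.5), (30, 56, 80))),
    ("STA", "vE", "sta_end", ((30, 56, 80), (29, 56, 90), (30, 55, 100))),
    ("LA", "vB", "la_end", ((34, 55, 56), (26, 57, 54), (18, 58, 52))),
    ("FA", "vC", "fa_end", ((32, 56, 63), (24, 57, 65), (15, 58, 70))),
    ("OA", "vD", "oa_end", ((31, 56, 71), (35, 57, 73), (39, 58, 75))),
    ("MA", "vE", "ma_end", ((30, 56, 80), (24, 57, 84), (17, 57, 88))),
)

DEFAULT_VESSEL_RADII = {"CCA": 3.0, "ICA": 2.4, "ECA": 2.2, "STA": 1.8,
                        "LA": 1.7, "FA": 1.7, "OA": 1.6, "MA": 1.7}

TRUTH_JUNCTIONS = {"vA": (40.0, 54.0, 46.0), "vB": (34.0, 55.0, 56.0),
                   "vC": (32.0, 56.0, 63.0), "vD": (31.0, 56.0, 71.0),
                   "vE": (30.0, 56.0, 80.0)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Acquisition geometry, intensity classes and deformation settings.

    Defaults follow a clinical CTA protocol: 0.43 x 0.43 mm in-plane pixels
    with a 0.5 mm slice interval.  Intensity classes are HU-like: dense bone
    around 1200, contrast-enhanced lumen around 350, soft-tissue background
    0, separable by simple windows.  ``blend_sigma`` is the width (mm) of
    the Gaussian kernel coupling bone motion to vessel deformation.
    """

    voxel_spacing: Tuple[float, float, float] = (0.43, 0.43, 0.5)
    fov_mm: Tuple[float, float, float] = (78.0, 70.0, 110.0)
    hu_bone: float = 1200.0
    hu_vessel: float = 350.0
    hu_background: float = 0.0
    segment_shape_params: dict = field(default_factory=lambda: copy.deepcopy(
        {k: tuple(v) for k, v in DEFAULT_SEGMENT_SHAPES.items()}))
    vessel_radii: dict = field(default_factory=lambda: dict(DEFAULT_VESSEL_RADII))
    blend_sigma: float = 25.0
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomConfigurationError("voxel spacing must be positive on all axes")
        if not (self.hu_bone > self.hu_vessel > self.hu_background):
            raise PhantomConfigurationError(
                "intensity classes must satisfy hu_bone > hu_vessel > hu_background")
        if self.blend_sigma <= 0:
            raise PhantomConfigurationError("blend_sigma must be positive")
        if self.noise_sd < 0:
            raise PhantomConfigurationError("noise_sd must be non-negative")
        missing = set(BRANCH_NAMES) - set(self.vessel_radii)
        if missing:
            raise PhantomConfigurationError(f"vessel_radii missing branches: {sorted(missing)}")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(f / s)) for f, s in zip(self.fov_mm, self.voxel_spacing))

    # intensity windows implied by the class levels
    @property
    def bone_threshold(self) -> float:
        return 0.5 * (self.hu_vessel + self.hu_bone)

    @property
    def inclusive_threshold(self) -> float:
        return 0.5 * (self.hu_background + self.hu_vessel)

    @classmethod
    def coarse(cls, seed: int = 0, **kw) -> "PhantomConfig":
        """Half-resolution variant for quick experiments and tests."""
        kw.setdefault("voxel_spacing", (0.86, 0.86, 1.0))
        return cls(seed=seed, **kw)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("voxel_spacing", "fov_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "segment_shape_params" in raw:
            raw["segment_shape_params"] = {
                name: tuple((k, tuple(a), tuple(b)) for k, a, b in spec)
                for name, spec in raw["segment_shape_params"].items()}
        return cls(**raw)


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class PhantomScene:
    """One pose of the phantom: bone segments, vessel, and ground truth."""

    config: PhantomConfig
    segments: Dict[str, SegmentModel]
    vessel: SegmentModel
    centerline_truth: CenterlineTree
    anatomical_hints: np.ndarray
    truth_transforms: Dict[str, RigidTransform]
    pose_index: int = 0
    solids: Dict[str, CompositeSolid] = field(default_factory=dict)
    branch_polylines: List[tuple] = field(default_factory=list)  # (branch, u, v, pts)
    bone_centroids: Dict[str, np.ndarray] = field(default_factory=dict)

    def truth_bifurcations(self) -> Dict[str, np.ndarray]:
        return self.centerline_truth.labeled_points()

    def segment_names(self):
        return list(self.segments)


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, points[:, k])
    return out


def blend_displacement(points, motions: Dict[str, RigidTransform],
                       centroids: Dict[str, np.ndarray], sigma: float) -> np.ndarray:
    """Normalized Gaussian-weighted blend of rigid segment motions.

    ``d(p) = sum_s w_s(p) (T_s p - p) / sum_s w_s(p)`` with
    ``w_s(p) = exp(-||p - c_s||^2 / sigma^2)``.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    num = np.zeros_like(pts)
    den = np.zeros(len(pts))
    for name, motion in motions.items():
        c = np.asarray(centroids[name], float)
        w = np.exp(-((pts - c) ** 2).sum(axis=1) / sigma ** 2)
        num += w[:, None] * (motion.apply(pts) - pts)
        den += w
    out = num / den[:, None]
    return out[0] if np.asarray(points).ndim == 1 else out


def _rasterize_capsule_edges(edges, radii, shape, spacing, origin) -> np.ndarray:
    """Union of capsules along polylines via a per-branch distance transform."""
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    mask = np.full(shape, False)
    step = float(spacing.min()) / 2.0
    for branch, _, _, pts in edges:
        r = float(radii[branch])
        fine = _resample_polyline(pts, step)
        lo = np.maximum(np.floor((fine.min(axis=0) - r - origin) / spacing).astype(int) - 2, 0)
        hi = np.minimum(np.ceil((fine.max(axis=0) + r - origin) / spacing).astype(int) + 3, shape)
        sub_shape = tuple(hi - lo)
        marked = np.full(sub_shape, True)
        idx = np.round((fine - origin) / spacing).astype(int) - lo
        idx = np.clip(idx, 0, np.asarray(sub_shape) - 1)
        marked[tuple(idx.T)] = False
        d = ndimage.distance_transform_edt(marked, sampling=spacing)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d <= r
    return mask


def _build_truth_tree(edges) -> CenterlineTree:
    tree = CenterlineTree()
    node_ids = {}
    for branch, u, v, pts in edges:
        for name, p in ((u, pts[0]), (v, pts[-1])):
            if name not in node_ids:
                node_ids[name] = len(node_ids)
                tree.add_node(node_ids[name], p)
        tree.add_edge(node_ids[u], node_ids[v], pts, branch=branch)
    tree.labels = {lab: node_ids[lab] for lab in BIFURCATION_LABELS if lab in node_ids}
    return tree


def _check_separation(masks: Dict[str, np.ndarray], context: str) -> None:
    """Segments must be disjoint AND non-adjacent (26-connectivity): masks
    that merely touch would fuse into one connected component and defeat
    region growing, exactly like insufficient manual separation would."""
    names = list(masks)
    union = np.zeros(next(iter(masks.values())).shape, dtype=bool)
    for m in masks.values():
        union |= m
    labels, n = ndimage.label(union, structure=np.ones((3, 3, 3), bool))
    if n >= len(names):
        return
    owner = {}
    for name in names:
        for lab in np.unique(labels[masks[name]]):
            if lab in owner and owner[lab] != name:
                raise PhantomConfigurationError(
                    f"segments '{owner[lab]}' and '{name}' touch or overlap ({context})")
            owner[lab] = name


def _check_bounds(name, lo, hi, config):
    margin = 2.0 * np.asarray(config.voxel_spacing)
    fov = np.asarray(config.fov_mm)
    if np.any(lo < margin) or np.any(hi > fov - margin):
        raise PhantomConfigurationError(
            f"segment '{name}' exceeds the field of view: bounds {lo.round(2)}..{hi.round(2)} "
            f"vs FOV {tuple(fov)} (2-voxel margin required)")


def generate_scene(config: Optional[PhantomConfig] = None) -> PhantomScene:
    """Build the pre-pose scene: 6 bone segments + vessel + ground truth.

    Deterministic for a fixed config (the seed only affects voxelization
    noise, not geometry).  Raises on overlapping or out-of-bounds segments.
    """
    config = config or PhantomConfig()
    shape = config.grid_shape
    spacing, origin = config.voxel_spacing, (0.0, 0.0, 0.0)

    solids = {name: _spec_to_solid(spec)
              for name, spec in config.segment_shape_params.items()}
    masks = {}
    for name, solid in solids.items():
        lo, hi = solid.bounds()
        _check_bounds(name, lo, hi, config)
        masks[name] = solid.rasterize(shape, spacing, origin)

    edges = [(branch, u, v, np.asarray(pts, float))
             for branch, u, v, pts in DEFAULT_BRANCH_EDGES]
    for branch, _, _, pts in edges:
        r = config.vessel_radii[branch]
        _check_bounds(branch, pts.min(axis=0) - r, pts.max(axis=0) + r, config)
    vessel_mask = _rasterize_capsule_edges(edges, config.vessel_radii, shape, spacing, origin)
    _check_separation({**masks, "vessel": vessel_mask}, "scene generation")

    segments = {}
    for name in BONE_NAMES:
        bm = BinaryMask(data=masks[name], spacing=spacing, origin=origin, label=name)
        segments[name] = extract_surface(bm, name=name)
    vm = BinaryMask(data=vessel_mask, spacing=spacing, origin=origin, label="vessel")
    vessel = extract_surface(vm, name="vessel")

    truth_edges = [(branch, u, v, _resample_polyline(pts, 1.0))
                   for branch, u, v, pts in edges]
    tree = _build_truth_tree(truth_edges)

    centroids = {name: np.asarray(segments[name].mesh.center_mass)
                 for name in BONE_NAMES}
    return PhantomScene(
        config=config, segments=segments, vessel=vessel, centerline_truth=tree,
        anatomical_hints=np.eye(3),
        truth_transforms={name: RigidTransform.identity() for name in BONE_NAMES},
        pose_index=0, solids=solids,
        branch_polylines=[(branch, u, v, pts) for branch, u, v, pts in edges],
        bone_centroids=centroids)


def displace_scene(scene: PhantomScene,
                   bone_motions: Dict[str, RigidTransform]) -> PhantomScene:
    """Post-pose scene: bones moved rigidly, vessel deformed by the blend.

    Requires one motion per bone segment (the maxillofacial motion moves the
    whole reference and is removed downstream by the global alignment).
    """
    missing = [n for n in BONE_NAMES if n not in bone_motions]
    if missing:
        raise PhantomConfigurationError(f"missing motion for segment(s): {missing}")
    config = scene.config
    shape = config.grid_shape
    spacing, origin = config.voxel_spacing, (0.0, 0.0, 0.0)

    segments = {}
    for name in BONE_NAMES:
        motion = bone_motions[name]
        solid = scene.solids[name].posed(motion)
        lo, hi = solid.bounds()
        _check_bounds(name, lo, hi, config)
        mask = BinaryMask(data=solid.rasterize(shape, spacing, origin),
                          spacing=spacing, origin=origin, label=name)
        moved = scene.segments[name].transformed(motion)
        segments[name] = SegmentModel(name=name, mesh=moved.mesh, mask=mask)
    motions = {n: bone_motions[n] for n in BONE_NAMES}
    centroids = scene.bone_centroids
    sigma = config.blend_sigma

    step = float(min(spacing)) / 2.0
    deformed_edges = []
    for branch, u, v, pts in scene.branch_polylines:
        fine = _resample_polyline(pts, step)
        fine = fine + blend_displacement(fine, motions, centroids, sigma)
        deformed_edges.append((branch, u, v, fine))
    for branch, _, _, pts in deformed_edges:
        r = config.vessel_radii[branch]
        _check_bounds(branch, pts.min(axis=0) - r, pts.max(axis=0) + r, config)
    vessel_mask = _rasterize_capsule_edges(deformed_edges, config.vessel_radii,
                                           shape, spacing, origin)
    _check_separation({**{n: segments[n].mask.data for n in BONE_NAMES},
                       "vessel": vessel_mask}, "after displacement")
    vm = BinaryMask(data=vessel_mask, spacing=spacing, origin=origin, label="vessel")
    vessel = extract_surface(vm, name="vessel")

    tree = CenterlineTree()
    for n, d in scene.centerline_truth.graph.nodes(data=True):
        p = d["point"]
        tree.add_node(n, p + blend_displacement(p, motions, centroids, sigma))
    for a, b, d in scene.centerline_truth.graph.edges(data=True):
        poly = d["polyline"]
        tree.add_edge(a, b, poly + blend_displacement(poly, motions, centroids, sigma),
                      d.get("radii"), d.get("branch", ""))
    tree.labels = dict(scene.centerline_truth.labels)

    return PhantomScene(
        config=config, segments=segments, vessel=vessel, centerline_truth=tree,
        anatomical_hints=scene.anatomical_hints.copy(),
        truth_transforms=motions, pose_index=1,
        solids={n: scene.solids[n].posed(bone_motions[n]) for n in BONE_NAMES},
        branch_polylines=deformed_edges, bone_centroids=centroids)


def truth_bifurcation_shifts(scene: PhantomScene,
                             bone_motions: Dict[str, RigidTransform]) -> Dict[str, np.ndarray]:
    """Analytic blend displacement at the stored vA-vE coordinates of a
    pre-pose scene (the ground truth for bifurcation tracking)."""
    centroids = scene.bone_centroids
    sigma = scene.config.blend_sigma
    return {lab: blend_displacement(p, bone_motions, centroids, sigma)
            for lab, p in scene.truth_bifurcations().items()}


def voxelize_scene(scene: PhantomScene,
                   config: Optional[PhantomConfig] = None) -> Tuple[VoxelVolume, VoxelVolume]:
    """Paint (contrast, non-contrast) volumes from the scene's masks.

    The contrast volume contains bone and vessel; the non-contrast volume
    bone only.  Gaussian intensity noise (``noise_sd``) is added with a
    stream derived from ``(config.seed, scene.pose_index)``, so a given
    scene voxelizes reproducibly and pre/post noise fields are independent.
    """
    config = config or scene.config
    shape = config.grid_shape
    bone_union = np.zeros(shape, dtype=bool)
    for name in BONE_NAMES:
        bone_union |= scene.segments[name].mask.data
    base = np.full(shape, config.hu_background, dtype=np.float32)
    base[bone_union] = config.hu_bone
    noncontrast = base.copy()
    contrast = base
    contrast[scene.vessel.mask.data] = config.hu_vessel

    vols = []
    for kind, data in (("contrast", contrast), ("noncontrast", noncontrast)):
        if config.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF,
                                        scene.pose_index, kind == "contrast"]))
            data = data + rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
        vols.append(VoxelVolume(data=data, spacing=config.voxel_spacing, origin=(0, 0, 0)))
    return vols[0], vols[1]


# ---------------------------------------------------------------------------
# motion sampling
# ---------------------------------------------------------------------------

#: per-segment centroid-shift magnitudes (mm) emulating a clinical cohort's
#: mean neck repositioning: small at C1, growing caudally to C4
COHORT_SHIFT_MAGNITUDES = {"maxillofacial": 0.0, "C1": 1.0, "C2": 2.2,
                           "C3": 4.3, "C4": 5.9, "mandible": 1.0}
COHORT_ROTATION_DEG = {"maxillofacial": 0.0, "C1": 0.8, "C2": 1.5,
                       "C3": 2.5, "C4": 3.5, "mandible": 1.0}


def sample_bone_motions(scene: PhantomScene, seed, scale: float = 1.0,
                        amplitude_jitter: float = 0.0,
                        skull_motion: bool = False) -> Dict[str, RigidTransform]:
    """Random per-segment rigid motions emulating neck repositioning.

    The cervical segments share a per-draw displacement direction (neck
    flexion/rotation moves the column coherently) with magnitudes growing
    from C1 to C4; each rotation is taken about the segment's own centroid,
    so the injected centroid shift equals the translation magnitude exactly.

    ``amplitude_jitter`` scales magnitudes per draw by a uniform factor in
    ``[1 - j, 1 + j]``; ``skull_motion`` adds a small fiducial motion that
    downstream global alignment must remove.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # flexion/rotation moves the column mostly in the sagittal plane, with
    # anteroposterior translation dominating — this also keeps the stacked
    # segments from being driven into each other
    u = rng.normal(size=3) * np.array([1.0, 0.3, 0.5])
    u /= np.linalg.norm(u)
    amp = scale * (1.0 + amplitude_jitter * rng.uniform(-1.0, 1.0))
    rot_axis = rng.normal(size=3)
    rot_axis /= np.linalg.norm(rot_axis)
    motions = {}
    for name in BONE_NAMES:
        c = scene.bone_centroids[name]
        mag = COHORT_SHIFT_MAGNITUDES[name] * amp
        ang = COHORT_ROTATION_DEG[name] * amp
        if name == "maxillofacial":
            if skull_motion:
                t = rng.normal(size=3)
                t = t / np.linalg.norm(t) * 1.0 * scale
                motions[name] = (RigidTransform.from_translation(t)
                                 @ RigidTransform.rotation_about(rng.normal(size=3), 1.0 * scale, pivot=c))
            else:
                motions[name] = RigidTransform.identity()
            continue
        jit = rng.normal(size=3) * 0.15
        direction = u + jit
        direction /= np.linalg.norm(direction)
        axis = rot_axis + rng.normal(size=3) * 0.2
        rot = RigidTransform.rotation_about(axis, ang, pivot=c)
        motions[name] = RigidTransform.from_translation(mag * direction) @ rot
    return motions


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_scene(scene: PhantomScene, outdir, write_volumes: bool = True) -> None:
    """Write STL surfaces, (optionally) volumes, and a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, seg in {**scene.segments, "vessel": scene.vessel}.items():
        seg.mesh.export(outdir / f"{name}.stl")
    if write_volumes:
        contrast, noncontrast = voxelize_scene(scene)
        contrast.write(outdir / "contrast.mha")
        noncontrast.write(outdir / "noncontrast.mha")
    truth = {
        "transforms": {n: t.matrix.tolist() for n, t in scene.truth_transforms.items()},
        "bifurcations": {lab: p.tolist() for lab, p in scene.truth_bifurcations().items()},
        "anatomical_hints": scene.anatomical_hints.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
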