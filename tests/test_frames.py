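import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from carotidshift.frames import (DisplacementRecord, FrameError, StandardFrame,
                                 center_of_gravity, euler_decompose,
                                 euler_recompose, inertia_axes, to_standard)
from carotidshift.geometry import RigidTransform
from carotidshift.segmentation import SegmentModel

WORLD_HINTS = np.eye(3)


def _box_model(extents, center=(0, 0, 0), transform=None):
    mesh = trimesh.creation.box(extents=extents)
    mesh.apply_translation(center)
    if transform is not None:
        mesh.vertices = transform.apply(mesh.vertices)
    return SegmentModel("box", mesh=mesh)


# ---------------------------------------------------------------------------
# center of gravity
# ---------------------------------------------------------------------------

def test_centroid_of_translated_cube():
    m = _box_model((1, 1, 1), center=(1, 2, 3))
    assert np.allclose(center_of_gravity(m), (1, 2, 3), atol=1e-12)


def test_centroid_of_symmetric_pair_is_midpoint():
    a = trimesh.creation.box(extents=(2, 2, 2))
    a.apply_translation((5, 0, 0))
    b = trimesh.creation.box(extents=(2, 2, 2))
    b.apply_translation((-5, 0, 0))
    m = SegmentModel("pair", mesh=trimesh.util.concatenate([a, b]))
    assert np.allclose(center_of_gravity(m), (0, 0, 0), atol=1e-9)


def test_mesh_and_voxel_centroids_agree_on_phantom(pre_scene):
    for name in ("maxillofacial", "C2", "mandible"):
        seg = pre_scene.segments[name]
        mesh_c = center_of_gravity(seg)
        vox_c = seg.mask.centroid()
        assert np.linalg.norm(mesh_c - vox_c) <= 0.5 * max(seg.mask.spacing), name


def test_centroid_requires_solid_or_mask():
    with pytest.raises(FrameError):
        center_of_gravity(SegmentModel("nothing"))


# ---------------------------------------------------------------------------
# inertia axes
# ---------------------------------------------------------------------------

def test_inertia_axes_of_axis_aligned_box():
    frame = inertia_axes(_box_model((20, 10, 5), center=(3, 4, 5)), WORLD_HINTS)
    assert np.allclose(np.abs(frame.axes), np.eye(3), atol=1e-9)
    assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-12)
    assert np.allclose(frame.origin, (3, 4, 5), atol=1e-9)


def test_inertia_axes_follow_a_known_rotation(rng):
    r0 = RigidTransform.from_euler_xyz(20.0, -10.0, 35.0, translation=(4, 1, -2))
    frame0 = inertia_axes(_box_model((20, 10, 5)), WORLD_HINTS)
    hints = r0.apply_vectors(WORLD_HINTS)
    frame1 = inertia_axes(_box_model((20, 10, 5), transform=r0), hints)
    assert np.allclose(frame1.axes, frame0.axes @ r0.rotation.T, atol=1e-6)


def test_inertia_equivariance_under_random_rigid_motions(pre_scene, rng):
    """frame(G . model, G . hints) = G . frame(model, hints)."""
    skull = pre_scene.segments["maxillofacial"]
    base = inertia_axes(skull, pre_scene.anatomical_hints)
    for k in range(5):
        g = RigidTransform.from_rotation_translation(
            Rotation.random(random_state=k).as_matrix(), rng.uniform(-20, 20, 3))
        moved = skull.transformed(g)
        frame = inertia_axes(moved, g.apply_vectors(pre_scene.anatomical_hints))
        assert np.allclose(frame.origin, g.apply(base.origin), atol=1e-6)
        assert np.allclose(frame.axes, base.axes @ g.rotation.T, atol=1e-6)


def test_phantom_skull_moments_match_voxel_oracle(pre_scene):
    """Second moments from the polyhedral integral vs brute-force voxel
    summation agree within 1%."""
    skull = pre_scene.segments["maxillofacial"]
    mesh_inertia = skull.mesh.moment_inertia / skull.mesh.volume
    pts = skull.mask.index_to_world(np.argwhere(skull.mask.data))
    pts = pts - pts.mean(axis=0)
    r2 = (pts ** 2).sum(axis=1)
    vox_inertia = (np.eye(3) * r2.sum() - pts.T @ pts) / len(pts)
    mw = np.sort(np.linalg.eigvalsh(mesh_inertia))
    vw = np.sort(np.linalg.eigvalsh(vox_inertia))
    assert np.all(np.abs(mw - vw) / vw < 0.01)


def test_degenerate_moments_rejected():
    sphere = SegmentModel("sphere", mesh=trimesh.creation.icosphere(3, radius=5.0))
    with pytest.raises(FrameError, match="symmetric"):
        inertia_axes(sphere, WORLD_HINTS)


def test_left_handed_hint_sets_are_corrected():
    # flipping one hint must still give a right-handed frame
    hints = np.array([[1, 0, 0], [0, -1, 0], [0, 0, 1]], dtype=float)
    frame = inertia_axes(_box_model((20, 10, 5)), hints)
    assert np.linalg.det(frame.axes) > 0


# ---------------------------------------------------------------------------
# conjugation into the standardized frame
# ---------------------------------------------------------------------------

def test_identity_frame_is_a_noop():
    frame = StandardFrame(origin=np.zeros(3), axes=np.eye(3))
    t = RigidTransform.from_euler_xyz(5, 3, -2, translation=(1, 2, 3))
    assert to_standard(t, frame).almost_equal(t, atol=1e-12)


def test_pure_translation_conjugates_to_rotated_translation(rng):
    axes = Rotation.random(random_state=7).as_matrix().T
    frame = StandardFrame(origin=rng.uniform(-5, 5, 3), axes=axes)
    t = np.array([2.0, -1.0, 0.5])
    t_m = to_standard(RigidTransform.from_translation(t), frame)
    assert np.allclose(t_m.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(t_m.translation, axes @ t, atol=1e-12)


def test_conjugation_preserves_rotation_angle(rng):
    axes = Rotation.random(random_state=3).as_matrix().T
    frame = StandardFrame(origin=rng.uniform(-50, 50, 3), axes=axes)
    for k in range(20):
        t = RigidTransform.from_rotation_translation(
            Rotation.random(random_state=100 + k).as_matrix(), rng.uniform(-5, 5, 3))
        assert abs(to_standard(t, frame).rotation_angle_deg()
                   - t.rotation_angle_deg()) < 1e-9


# ---------------------------------------------------------------------------
# Euler parameterization
# ---------------------------------------------------------------------------

def test_translation_components_read_off_directly():
    t = RigidTransform.from_translation((1.0, 2.0, 3.0))
    rec = euler_decompose(t, pivot=(10, 20, 30))
    assert (rec.dx, rec.dy, rec.dz) == (1.0, 2.0, 3.0)
    assert rec.dalpha == rec.dbeta == rec.dgamma == 0.0


def test_rotation_order_alpha_beta_gamma_about_pivot():
    pivot = (5.0, -3.0, 8.0)
    t = RigidTransform.from_euler_xyz(1.0, 2.0, 3.0, pivot=pivot)
    rec = euler_decompose(t, pivot)
    assert np.allclose([rec.dalpha, rec.dbeta, rec.dgamma], [1.0, 2.0, 3.0], atol=1e-9)
    assert np.allclose([rec.dx, rec.dy, rec.dz], 0.0, atol=1e-9)


def test_euler_roundtrip_on_many_small_rotations(rng):
    pivot = np.array([4.0, -2.0, 7.0])
    max_err = 0.0
    for _ in range(1000):
        angles = rng.uniform(-15, 15, 3)
        t = RigidTransform.from_euler_xyz(*angles, translation=rng.uniform(-5, 5, 3),
                                          pivot=pivot)
        rec = euler_decompose(t, pivot)
        back = euler_recompose(rec, pivot)
        max_err = max(max_err, float(np.abs(back.matrix - t.matrix).max()))
        assert np.allclose([rec.dalpha, rec.dbeta, rec.dgamma], angles, atol=1e-9)
    assert max_err < 1e-9


def test_gimbal_lock_reported():
    t = RigidTransform.from_euler_xyz(10.0, 90.0, 5.0)
    with pytest.raises(FrameError, match="beta"):
        euler_decompose(t, (0, 0, 0))


def test_angles_stay_in_half_open_interval(rng):
    for k in range(50):
        t = RigidTransform.from_rotation_translation(
            Rotation.random(random_state=k).as_matrix(), (0, 0, 0))
        try:
            rec = euler_decompose(t, (0, 0, 0))
        except FrameError:
            continue  # gimbal-locked draws are legitimately rejected
        for a in (rec.dalpha, rec.dbeta, rec.dgamma):
            assert -180.0 < a <= 180.0


# ---------------------------------------------------------------------------
# frame invariance of scalar shifts
# ---------------------------------------------------------------------------

def test_shift_norms_identical_in_both_frames(analysis):
    for rec_p, rec_s in zip(analysis.records_pcs.values(), analysis.records_scs.values()):
        assert abs(rec_p.translation_norm() - rec_s.translation_norm()) < 1e-9
    for sp, ss in zip(analysis.shifts_pcs, analysis.shifts_scs):
        assert abs(sp.norm - ss.norm) < 1e-9


def test_displacement_record_translation_helpers():
    rec = DisplacementRecord(segment="C1", frame="SCS", dx=3.0, dy=4.0, dz=0.0)
    assert rec.translation_norm() == pytest.approx(5.0)
    assert rec.dalpha is None
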