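import numpy as np
import pytest

from carotidshift.phantom import BONE_NAMES, CompositeSolid, Ellipsoid
from carotidshift.segmentation import (DiceReport, SegmentationError, dice,
                                       extract_surface, region_grow,
                                       resample_mask, subtract_masks,
                                       threshold_mask)
from carotidshift.geometry import RigidTransform
from carotidshift.volume import BinaryMask, GridMismatchError, VoxelVolume


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def _mask(data, spacing=(1.0, 1.0, 1.0), label="m"):
    return BinaryMask(data=np.asarray(data, dtype=bool), spacing=spacing, label=label)


# ---------------------------------------------------------------------------
# thresholding and subtraction
# ---------------------------------------------------------------------------

def test_threshold_window_inclusion():
    v = _vol(np.full((4, 4, 4), 100.0))
    assert threshold_mask(v, 50, 150).count() == 64
    with pytest.warns(UserWarning):
        empty = threshold_mask(v, 200, 300)
    assert empty.count() == 0


def test_threshold_empty_window_rejected():
    v = _vol(np.zeros((2, 2, 2)))
    with pytest.raises(SegmentationError):
        threshold_mask(v, 10, 10)


def test_bone_window_on_noiseless_phantom_equals_truth(pre_scene):
    from dataclasses import replace
    from carotidshift import voxelize_scene
    cfg = replace(pre_scene.config, noise_sd=0.0)
    contrast, _ = voxelize_scene(pre_scene, cfg)
    got = threshold_mask(contrast, cfg.bone_threshold, cfg.hu_bone + 1)
    union = np.zeros(cfg.grid_shape, dtype=bool)
    for n in BONE_NAMES:
        union |= pre_scene.segments[n].mask.data
    assert np.array_equal(got.data, union)


def test_subtract_identities(rng):
    a = _mask(rng.random((6, 6, 6)) > 0.5)
    assert subtract_masks(a, a).count() == 0
    b = _mask(np.zeros((6, 6, 6)))
    assert np.array_equal(subtract_masks(a, b).data, a.data)
    # set identity: (a - b) | b reconstructs a | b
    c = _mask(rng.random((6, 6, 6)) > 0.5)
    recon = subtract_masks(a, c).data | c.data
    assert np.array_equal(recon, a.data | c.data)


def test_subtract_requires_same_grid():
    a = _mask(np.ones((4, 4, 4)))
    b = _mask(np.ones((4, 4, 4)), spacing=(2.0, 1.0, 1.0))
    with pytest.raises(GridMismatchError):
        subtract_masks(a, b)


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------

def test_region_grow_keeps_seeded_component():
    data = np.zeros((12, 12, 12), bool)
    data[1:4, 1:4, 1:4] = True     # cube A
    data[7:10, 7:10, 7:10] = True  # cube B
    m = _mask(data)
    grown = region_grow(m, (2.0, 2.0, 2.0))
    assert grown.count() == 27
    assert grown.data[2, 2, 2] and not grown.data[8, 8, 8]
    # single-component mask is returned unchanged
    solo = _mask(data[:6, :6, :6])
    assert np.array_equal(region_grow(solo, (2, 2, 2)).data, solo.data)


def test_region_grow_after_bridge_deletion():
    """A 1-voxel bridge between two bodies, removed as manual editing
    would, leaves region growing with the seeded body only."""
    data = np.zeros((20, 8, 8), bool)
    data[1:6, 1:6, 1:6] = True
    data[10:15, 1:6, 1:6] = True
    bridge = (slice(6, 10), 3, 3)
    data[bridge] = True
    m = _mask(data)
    merged = region_grow(m, (2, 2, 2))
    assert merged.count() == data.sum()          # bridge connects everything
    data[bridge] = False                         # emulate manual deletion
    cleaned = region_grow(_mask(data), (2, 2, 2))
    assert cleaned.count() == 125


def test_region_grow_seed_errors():
    m = _mask(np.zeros((4, 4, 4)))
    m.data[1, 1, 1] = True
    with pytest.raises(SegmentationError, match=r"\(3, 3, 3\)"):
        region_grow(m, (3.0, 3.0, 3.0))
    with pytest.raises(SegmentationError):
        region_grow(m, (40.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def test_surface_of_voxelized_sphere_has_analytic_volume():
    sphere = CompositeSolid([Ellipsoid((15, 15, 15), (5, 5, 5))])
    m = BinaryMask(data=sphere.rasterize((60, 60, 60), (0.5, 0.5, 0.5)),
                   spacing=(0.5, 0.5, 0.5), label="sphere")
    mesh = extract_surface(m).mesh
    true = 4.0 / 3.0 * np.pi * 125
    assert mesh.is_watertight
    assert abs(mesh.volume - true) / true < 0.02


def test_surface_of_single_voxel_is_closed():
    # smallest possible input: marching cubes yields the octahedron through
    # the face-neighbour midpoints (volume h^3/6) — closed, orientable,
    # strictly positive
    data = np.zeros((5, 5, 5), bool)
    data[2, 2, 2] = True
    mesh = extract_surface(_mask(data)).mesh
    assert mesh.is_watertight
    assert mesh.volume == pytest.approx(1.0 / 6.0, rel=1e-6)


def test_all_phantom_surfaces_watertight(pre_scene):
    for seg in list(pre_scene.segments.values()) + [pre_scene.vessel]:
        assert seg.mesh.is_watertight, seg.name
        assert seg.mesh.volume > 0


def test_empty_mask_has_no_surface():
    with pytest.raises(SegmentationError):
        extract_surface(_mask(np.zeros((3, 3, 3))))


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_dice_identical_disjoint_and_shifted():
    a = np.zeros((8, 8, 8), bool)
    a[1:3, 1:3, 1:3] = True               # 2x2x2 cube
    b = np.zeros_like(a)
    b[2:4, 1:3, 1:3] = True               # shifted one voxel in x: overlap 4
    ra = dice(_mask(a), _mask(a))
    assert ra.s == 1.0 and ra.passed
    rd = dice(_mask(a), _mask(~a & False | np.roll(a, 4, axis=0)))
    assert rd.s == 0.0 and not rd.passed
    rs = dice(_mask(a), _mask(b))
    assert rs.s == pytest.approx(2 * 4 / (8 + 8))
    assert rs.volume_a == pytest.approx(8.0)


def test_dice_symmetry(rng):
    for _ in range(10):
        a = _mask(rng.random((6, 6, 6)) > 0.4)
        b = _mask(rng.random((6, 6, 6)) > 0.6)
        if a.count() + b.count() == 0:
            continue
        assert dice(a, b).s == dice(b, a).s


def test_dice_undefined_for_two_empty_masks():
    e = _mask(np.zeros((3, 3, 3)))
    with pytest.raises(SegmentationError):
        dice(e, e)


def test_dice_report_range_enforced():
    with pytest.raises(ValueError):
        DiceReport(s=1.2, volume_a=1, volume_b=1, passed=True)


def test_bone_dice_above_gate_under_strong_noise(pre_scene):
    """With intensity noise at 10% of the bone-background contrast the
    segmentation chain still recovers each bone at s > 0.95."""
    from dataclasses import replace
    from carotidshift import voxelize_scene
    from carotidshift.pipeline import _interior_seed, segment_volumes
    cfg = replace(pre_scene.config, noise_sd=0.1 * (pre_scene.config.hu_bone
                                                    - pre_scene.config.hu_background))
    contrast, noncontrast = voxelize_scene(pre_scene, cfg)
    seeds = {n: _interior_seed(pre_scene.segments[n].mask) for n in BONE_NAMES}
    models = segment_volumes(contrast, noncontrast, cfg, seeds,
                             _interior_seed(pre_scene.vessel.mask))
    for n in BONE_NAMES:
        assert dice(pre_scene.segments[n].mask, models[n].mask).s > 0.95, n


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_roundtrips_a_translated_mask():
    data = np.zeros((16, 16, 16), bool)
    data[4:9, 4:9, 4:9] = True
    m = _mask(data)
    t = RigidTransform.from_translation((3.0, -2.0, 1.0))
    moved = resample_mask(m, t, m)
    back = resample_mask(moved, t.inverse(), m)
    assert dice(m, back).s == 1.0
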