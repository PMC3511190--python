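"""End-to-end analysis of a phantom scene pair, and cohort experiments.

``analyze_pair`` runs the full measurement chain on a (pre, post) scene
pair exactly as it would run on paired CTA/CT acquisitions:

1. voxelize both scenes to contrast / non-contrast volumes;
2. segment: bone by thresholding the non-contrast volume, vessel by Boolean
   subtraction of bone from the thresholded contrast volume, each segment
   isolated by region growing from a seed, surfaces by marching cubes;
3. register: global fiducial (maxillofacial) ICP alignment ``T``, then
   per-segment ICP superimpositions; Dice QA of each aligned segmentation;
4. standardize: inertia frame of the reference maxillofacial model;
   per-segment displacements decomposed into (dx, dy, dz, dalpha, dbeta,
   dgamma) in scanner (PCS) and standardized (SCS) frames;
5. track: centerlines of both vessel masks, bifurcations labeled vA-vE,
   per-bifurcation displacement in both frames.

``recovery_experiment`` runs that chain over a phantom cohort with sampled
motions and reports how well every ground-truth quantity is recovered;
``simulate_cohort_truth`` generates the analytic (voxel-free) cohort used
for regression recovery at larger n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as _stats
from .centerline import (BifurcationShift, CenterlineTree, bifurcation_shifts,
                         extract_centerline, label_bifurcations)
from .frames import (DisplacementRecord, StandardFrame, center_of_gravity,
                     euler_decompose, inertia_axes, to_standard)
from .geometry import RigidTransform
from .phantom import (BONE_NAMES, PhantomConfig, PhantomScene, displace_scene,
                      generate_scene, sample_bone_motions, voxelize_scene)
from .registration import (IcpResult, IcpSettings, global_align, icp,
                           per_segment_transform)
from .segmentation import (DiceReport, SegmentModel, dice, extract_surface,
                           region_grow, resample_mask, subtract_masks,
                           threshold_mask)
from .volume import BinaryMask, VoxelVolume

MOBILE_SEGMENTS = ("C1", "C2", "C3", "C4", "mandible")


def _interior_seed(mask: BinaryMask) -> np.ndarray:
    """A point safely inside the mask (centroid, or the EDT maximum when the
    centroid falls outside a non-convex segment)."""
    c = mask.centroid()
    idx = np.round(mask.world_to_index(c)).astype(int)
    idx = np.clip(idx, 0, np.asarray(mask.shape) - 1)
    if mask.data[tuple(idx)]:
        return c
    d = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return mask.index_to_world(np.unravel_index(int(d.argmax()), mask.shape))


def segment_volumes(contrast: VoxelVolume, noncontrast: VoxelVolume,
                    config: PhantomConfig, bone_seeds: Dict[str, np.ndarray],
                    vessel_seed: np.ndarray,
                    smooth_sigma_vox: float = 0.8) -> Dict[str, SegmentModel]:
    """Threshold + subtraction + region growing + surfaces for one data set.

    Registration surfaces are extracted anti-aliased (see
    :func:`carotidshift.segmentation.extract_surface`): binary-lattice
    terracing otherwise biases the ICP rotations by several tenths of a
    degree.
    """
    contrast.require_same_grid(noncontrast)
    upper = float(max(contrast.data.max(), noncontrast.data.max())) + 1.0
    bones = threshold_mask(noncontrast, config.bone_threshold, upper, label="bones")
    inclusive = threshold_mask(contrast, config.inclusive_threshold, upper, label="bones+vessel")
    vessel_raw = subtract_masks(inclusive, bones, label="vessel")
    models: Dict[str, SegmentModel] = {}
    for name, seed in bone_seeds.items():
        models[name] = extract_surface(region_grow(bones, seed, label=name), name=name,
                                       smooth_sigma_vox=smooth_sigma_vox)
    models["vessel"] = extract_surface(region_grow(vessel_raw, vessel_seed, label="vessel"),
                                       name="vessel", smooth_sigma_vox=smooth_sigma_vox)
    return models


@dataclass
class PairAnalysis:
    """Everything measured from one (pre, post) acquisition pair."""

    global_alignment: IcpResult
    per_segment: Dict[str, IcpResult]            # superimposition matrices
    displacements: Dict[str, RigidTransform]     # forward per-segment T_l (PCS)
    records_pcs: Dict[str, DisplacementRecord]
    records_scs: Dict[str, DisplacementRecord]
    centroid_shifts: Dict[str, float]
    dice_reports: Dict[str, DiceReport]
    frame: StandardFrame
    shifts_pcs: List[BifurcationShift]
    shifts_scs: List[BifurcationShift]
    pre_tree: CenterlineTree
    post_tree_aligned: CenterlineTree
    pre_models: Dict[str, SegmentModel] = field(default_factory=dict)

    def shift_row(self) -> Dict[str, float]:
        """One shift-table row: centroid-shift norms + bifurcation norms."""
        row = {name: self.centroid_shifts[name] for name in MOBILE_SEGMENTS}
        row.update({s.label: s.norm for s in self.shifts_pcs})
        return row


def analyze_pair(pre_scene: PhantomScene, post_scene: PhantomScene,
                 icp_settings: Optional[IcpSettings] = None,
                 spur_factor: float = 2.0) -> PairAnalysis:
    """Run the full segmentation -> registration -> frames -> centerline
    chain on a scene pair, using each scene's stored masks only to place
    seeds (standing in for the interactive seeding of clinical software)."""
    settings = icp_settings or IcpSettings()
    config = pre_scene.config
    models, vols = {}, {}
    for key, scene in (("pre", pre_scene), ("post", post_scene)):
        contrast, noncontrast = voxelize_scene(scene, scene.config)
        seeds = {name: _interior_seed(scene.segments[name].mask) for name in BONE_NAMES}
        vseed = _interior_seed(scene.vessel.mask)
        models[key] = segment_volumes(contrast, noncontrast, scene.config, seeds, vseed)
        vols[key] = (contrast, noncontrast)

    pre_m, post_m = models["pre"], models["post"]
    g = global_align(post_m, pre_m, settings)
    t_global = g.transform
    post_aligned = {name: seg.transformed(t_global) for name, seg in post_m.items()}

    per_segment: Dict[str, IcpResult] = {}
    displacements: Dict[str, RigidTransform] = {}
    dice_reports: Dict[str, DiceReport] = {}
    for name in MOBILE_SEGMENTS + ("vessel",):
        res = per_segment_transform(name, post_aligned, pre_m, settings)
        per_segment[name] = res
        displacements[name] = res.transform.inverse()
        total = res.transform @ t_global  # post world -> pre world
        moved_mask = resample_mask(post_m[name].mask, total, pre_m[name].mask)
        dice_reports[name] = dice(pre_m[name].mask, moved_mask)
    dice_reports["maxillofacial"] = dice(
        pre_m["maxillofacial"].mask,
        resample_mask(post_m["maxillofacial"].mask, t_global, pre_m["maxillofacial"].mask))

    frame = inertia_axes(pre_m["maxillofacial"], pre_scene.anatomical_hints)
    records_pcs, records_scs, centroid_shifts = {}, {}, {}
    for name in MOBILE_SEGMENTS:
        c = center_of_gravity(pre_m[name])
        t_l = displacements[name]
        records_pcs[name] = euler_decompose(t_l, c, segment=name, frame="PCS")
        t_m = to_standard(t_l, frame)
        records_scs[name] = euler_decompose(t_m, frame.to_scs(c), segment=name, frame="SCS")
        centroid_shifts[name] = float(np.linalg.norm(t_l.apply(c) - c))

    pre_tree = extract_centerline(pre_m["vessel"], spur_factor=spur_factor)
    label_bifurcations(pre_tree, pre_scene.centerline_truth.labeled_points())
    post_tree = extract_centerline(post_m["vessel"], spur_factor=spur_factor)
    post_tree = post_tree.transformed(t_global)
    post_templates = {lab: t_global.apply(p)
                      for lab, p in post_scene.centerline_truth.labeled_points().items()}
    label_bifurcations(post_tree, post_templates)

    shifts_pcs = bifurcation_shifts(pre_tree, post_tree, frame=None)
    shifts_scs = bifurcation_shifts(pre_tree, post_tree, frame=frame)

    return PairAnalysis(global_alignment=g, per_segment=per_segment,
                        displacements=displacements, records_pcs=records_pcs,
                        records_scs=records_scs, centroid_shifts=centroid_shifts,
                        dice_reports=dice_reports, frame=frame,
                        shifts_pcs=shifts_pcs, shifts_scs=shifts_scs,
                        pre_tree=pre_tree, post_tree_aligned=post_tree,
                        pre_models=pre_m)


def truth_relative_transforms(motions: Dict[str, RigidTransform]) -> Dict[str, RigidTransform]:
    """Ground-truth per-segment displacements after removal of the fiducial
    motion: ``S_s = M_skull^-1 M_s``."""
    inv = motions["maxillofacial"].inverse()
    return {name: inv @ motions[name] for name in motions if name != "maxillofacial"}


def truth_aligned_bifurcation_shifts(pre_scene: PhantomScene, post_scene: PhantomScene
                                     ) -> Dict[str, np.ndarray]:
    """Truth bifurcation displacement in the reference frame: deformed truth
    points mapped back by the inverse fiducial motion, minus pre points."""
    inv = post_scene.truth_transforms["maxillofacial"].inverse()
    pre = pre_scene.truth_bifurcations()
    post = post_scene.truth_bifurcations()
    return {lab: inv.apply(post[lab]) - pre[lab] for lab in pre}


# ---------------------------------------------------------------------------
# cohort experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Ground-truth recovery over a phantom cohort."""

    n_subjects: int
    seed: int
    shift_table: pd.DataFrame                 # measured norms per subject
    injected_table: pd.DataFrame              # injected truth norms
    summary: pd.DataFrame
    rotation_errors: pd.DataFrame             # deg, per subject x segment
    translation_errors: pd.DataFrame          # mm (at segment centroid)
    dice_table: pd.DataFrame
    bifurcation_errors: pd.DataFrame          # mm, measured vs analytic truth
    fits: Dict[Tuple[str, str], "_stats.RegressionFit"]

    @property
    def max_rotation_error_deg(self) -> float:
        return float(self.rotation_errors.values.max())

    @property
    def max_translation_error_mm(self) -> float:
        return float(self.translation_errors.values.max())

    @property
    def min_dice(self) -> float:
        return float(self.dice_table.values.min())

    @property
    def max_bifurcation_error_mm(self) -> float:
        return float(self.bifurcation_errors.values.max())


def sample_admissible_motions(pre: PhantomScene, rng, motion_scale: float,
                               amplitude_jitter: float, skull_motion: bool,
                               max_attempts: int = 20):
    """Draw motions until the displaced scene is admissible (segments stay
    separated and inside the field of view) — necks do not interpenetrate,
    so inadmissible draws are rejected, not clipped."""
    last = None
    for _ in range(max_attempts):
        motions = sample_bone_motions(pre, rng, scale=motion_scale,
                                      amplitude_jitter=amplitude_jitter,
                                      skull_motion=skull_motion)
        try:
            return motions, displace_scene(pre, motions)
        except Exception as err:  # inadmissible draw
            last = err
    raise RuntimeError(f"no admissible motion draw in {max_attempts} attempts: {last}")


def recovery_experiment(n_subjects: int = 6, motion_scale: float = 1.0, seed: int = 0,
                        config: Optional[PhantomConfig] = None,
                        skull_motion: bool = True,
                        amplitude_jitter: float = 0.4) -> RecoveryReport:
    """Generate a cohort of phantom pairs, run the full pipeline on each,
    and report transform, Dice, bifurcation-shift and regression recovery.

    The default configuration is the half-resolution phantom; one shared
    anatomy is reused across subjects with independently sampled motions
    and noise streams.
    """
    if n_subjects < 6:
        raise ValueError("need at least 6 subjects")
    config = config or PhantomConfig.coarse(seed=seed)
    base = generate_scene(config)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)

    rows_meas, rows_truth, rot_err, tr_err, dice_rows, bif_err = {}, {}, {}, {}, {}, {}
    records_by_subject = {}
    comp_rows = {}
    for i, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        cfg_i = replace(config, seed=int(child.generate_state(1)[0] & 0x7FFFFFFF))
        pre = replace(base, config=cfg_i)
        motions, post = sample_admissible_motions(
            pre, rng, motion_scale, amplitude_jitter, skull_motion)
        ana = analyze_pair(pre, post)

        rows_meas[i] = ana.shift_row()
        truth_rel = truth_relative_transforms(motions)
        truth_shifts = truth_aligned_bifurcation_shifts(pre, post)
        rows_truth[i] = {**{n: float(np.linalg.norm(
                                truth_rel[n].apply(pre.bone_centroids[n]) - pre.bone_centroids[n]))
                            for n in MOBILE_SEGMENTS},
                         **{lab: float(np.linalg.norm(d)) for lab, d in truth_shifts.items()}}
        rot_err[i] = {n: (truth_rel[n].inverse() @ ana.displacements[n]).rotation_angle_deg()
                      for n in MOBILE_SEGMENTS}
        tr_err[i] = {n: float(np.linalg.norm(
                        ana.displacements[n].apply(pre.bone_centroids[n])
                        - truth_rel[n].apply(pre.bone_centroids[n])))
                     for n in MOBILE_SEGMENTS}
        dice_rows[i] = {n: r.s for n, r in ana.dice_reports.items()}
        bif_err[i] = {s.label: abs(s.norm - float(np.linalg.norm(truth_shifts[s.label])))
                      for s in ana.shifts_pcs}
        records_by_subject[i] = ana.records_scs
        comp_rows[i] = {f"{s.label}_{c}": s.delta[k]
                        for s in ana.shifts_scs for k, c in enumerate(("dx", "dy", "dz"))}

    shift_table = _stats.shift_table_from_records(rows_meas)
    injected = _stats.shift_table_from_records(rows_truth)
    x = _stats.build_regressors(records_by_subject)
    comps = pd.DataFrame.from_dict(comp_rows, orient="index")
    fits = _stats.fit_all_targets(x, comps)

    return RecoveryReport(
        n_subjects=n_subjects, seed=seed,
        shift_table=shift_table, injected_table=injected,
        summary=_stats.summarize(shift_table),
        rotation_errors=pd.DataFrame.from_dict(rot_err, orient="index"),
        translation_errors=pd.DataFrame.from_dict(tr_err, orient="index"),
        dice_table=pd.DataFrame.from_dict(dice_rows, orient="index"),
        bifurcation_errors=pd.DataFrame.from_dict(bif_err, orient="index"),
        fits=fits)


@dataclass
class CohortTruth:
    """Analytic (voxel-free) cohort: regressors, SCS bifurcation components
    and shift norms derived directly from sampled ground-truth motions."""

    regressors: pd.DataFrame
    components: pd.DataFrame
    norms: pd.DataFrame


def simulate_cohort_truth(n_subjects: int, seed: int = 0,
                          scene: Optional[PhantomScene] = None,
                          motion_scale: float = 1.0,
                          amplitude_jitter: float = 0.5) -> CohortTruth:
    """Sample a cohort of bone motions and evaluate the exact standardized
    displacement records and bifurcation shifts (no imaging chain).

    Used for regression-recovery experiments at n beyond what voxel
    pipelines need to demonstrate.
    """
    from .phantom import truth_bifurcation_shifts
    scene = scene or generate_scene(PhantomConfig.coarse())
    frame = inertia_axes(scene.segments["maxillofacial"], scene.anatomical_hints)
    ss = np.random.SeedSequence(seed)
    records_by_subject, comp_rows, norm_rows = {}, {}, {}
    for i, child in enumerate(ss.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        motions = sample_bone_motions(scene, rng, scale=motion_scale,
                                      amplitude_jitter=amplitude_jitter,
                                      skull_motion=False)
        recs = {}
        for name in MOBILE_SEGMENTS:
            c = scene.bone_centroids[name]
            t_m = to_standard(motions[name], frame)
            recs[name] = euler_decompose(t_m, frame.to_scs(c), segment=name, frame="SCS")
        records_by_subject[i] = recs
        shifts = truth_bifurcation_shifts(scene, motions)
        comp_rows[i] = {f"{lab}_{c}": float((frame.axes @ d)[k])
                        for lab, d in shifts.items() for k, c in enumerate(("dx", "dy", "dz"))}
        norm_rows[i] = {**{n: recs[n].translation_norm() for n in MOBILE_SEGMENTS},
                        **{lab: float(np.linalg.norm(d)) for lab, d in shifts.items()}}
    return CohortTruth(regressors=_stats.build_regressors(records_by_subject),
                       components=pd.DataFrame.from_dict(comp_rows, orient="index"),
                       norms=pd.DataFrame.from_dict(norm_rows, orient="index"))


def predicted_observed_r(fits: Dict, regressors: pd.DataFrame,
                         components: pd.DataFrame) -> float:
    """Pooled Pearson correlation between model-predicted and observed
    bifurcation components across all 15 targets."""
    pred, obs = [], []
    x = regressors.loc[components.index, list(_stats.REGRESSOR_NAMES)].values
    for (lab, comp), fit in fits.items():
        pred.append(fit.predict(x))
        obs.append(components[f"{lab}_{comp}"].values)
    pred, obs = np.concatenate(pred), np.concatenate(obs)
    return float(np.corrcoef(pred, obs)[0, 1])
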