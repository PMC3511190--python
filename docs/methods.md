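# Methods

## Problem and measurement model

Between two CT-angiography (CTA) acquisitions of the same head and neck,
each bone is treated as a rigid body and the carotid artery (CA) as soft
tissue whose deformation is driven by the surrounding bones.  The
quantities of interest are, per acquisition pair:

- the rigid displacement of each mobile segment (C1–C4, mandible) after
  the global head motion has been removed by aligning the maxillofacial
  (fiducial) segment;
- the 3D displacement of the five external-carotid bifurcations vA–vE;
- both expressed in a standardized coordinate system (SCS) anchored to the
  patient's own maxillofacial anatomy, so values are comparable across
  patients and scanner positions.

The pipeline is segmentation → surface registration → frame
standardization → centerline tracking → cohort statistics.  Each stage and
its numerical choices are described below; the digital phantom supplies
exact ground truth for all of them.

## Digital neck phantom

### Geometry

The phantom scene contains six bones and one vessel tree in a
78 × 70 × 110 mm field of view (x ≈ posterior, y ≈ left, z ≈ superior):

- **maxillofacial** fiducial: a union of four ellipsoids (≈ 17 cm³);
- **mandible**: ellipsoid body, two rami, an off-midline chin lump;
- **C1–C4**: each an elliptical body (26 × 18 × 11 mm) with a posterior
  spinous process and two side lumps whose sides alternate down the
  column; bodies are 14 mm apart, leaving ≈ 4 mm inter-vertebral
  clearance.
- **carotid tree**: capsules (radius 1.6–3.0 mm) along branch polylines —
  CCA rising to the vA bifurcation, ICA continuing superiorly, and the ECA
  giving off LA (vB), FA (vC), OA (vD) and MA (vE) before continuing as
  the STA.

Every primitive is rounded and at least ~6 voxels across, and all segments
are deliberately asymmetric.  Both choices are load-bearing: principal
inertia moments must be pairwise distinct (≥ 5 %) so the standardized
frame is unique, and surfaces must constrain all six rigid degrees of
freedom, because near-symmetric or sub-voxel features make surface
registration measurably biased (see *Registration accuracy* below).

Scene generation validates that segments stay inside the field of view
(2-voxel margin) and are pairwise non-adjacent under 26-connectivity —
segments that merely touch would fuse into one connected component and
defeat region growing, the same failure the clinical workflow avoids by
manual editing.

### Vessel deformation model

No quantitative vessel-tissue mechanics is assumed; the rigid-surroundings
assumption is instantiated as a normalized Gaussian-weighted blend of the
bone motions.  A centerline point p moves by

    d(p) = Σ_s w_s(p) (T_s p − p) / Σ_s w_s(p),
    w_s(p) = exp(−‖p − c_s‖² / σ²)

over the six bone segments s with pre-pose centroids c_s and rigid motions
T_s.  The kernel width σ (`blend_sigma`) defaults to 25 mm — of the order
of the inter-vertebral spacing, so each bifurcation responds mostly to the
two or three nearest bones.  No measured value exists for σ; it is
exposed as configuration.  The blend makes every bifurcation displacement
an exactly evaluable, smooth, deterministic function of the bone motions:
ground truth for tracking, and a recoverable signal for the regression.
The vessel surface is re-tubed around the deformed centerline (the lumen
radius is preserved; real arteries also change cross-section, which this
model deliberately omits).

### Voxelization and intensity model

Scenes voxelize at 0.43 × 0.43 mm pixels with a 0.5 mm slice interval
(clinical CTA protocol; `PhantomConfig.coarse()` halves the resolution for
fast experiments).  Intensities are HU-like class levels — bone 1200,
contrast-enhanced lumen 350, background 0 — with additive Gaussian noise
(default SD 15, a typical soft-reconstruction CT noise level).  There is
no partial-volume averaging, beam hardening, metal artifact or motion
blur: class separability is by construction, so segmentation-threshold
selection is not part of what the phantom can test.  At the default noise
level the binary masks recovered by thresholding are exact; the test suite
additionally checks the Dice gate at 10 % of the bone–background contrast
(SD 120).

### Motion sampling

`sample_bone_motions` emulates neck repositioning: the cervical segments
share a per-draw displacement direction (dominantly anteroposterior, the
sagittal pattern of flexion), with centroid-shift magnitudes growing down
the column — 1.0, 2.2, 4.3, 5.9 mm for C1…C4 and 1.0 mm for the mandible,
matching the mean magnitudes reported for a six-patient clinical cohort —
and rotations of 0.8–3.5° about per-segment axes through each segment's
own centroid (so the injected centroid shift equals the translation
magnitude exactly).  An optional fiducial motion (1° / 1 mm) exercises the
global alignment.  Draws whose masks would touch or leave the grid are
rejected and resampled (`sample_admissible_motions`); necks do not
interpenetrate.

## Segmentation

Bone = non-contrast volume thresholded at the bone/lumen midpoint
(775 HU-like); bone+vessel = contrast volume thresholded at the
lumen/background midpoint (175); vessel = Boolean difference.  Region
growing keeps the 26-connected component around a seed (the most
permissive connectivity).  Dice uses voxel overlap of co-registered masks,
2|A∩B|/(|A|+|B|), with the moving mask resampled nearest-neighbour onto
the reference grid; volumes of both masks are reported alongside.  The
pass mark is s > 0.95.

Surfaces are marching-cubes iso-surfaces at the 0.5 level.  For
registration the binary field is first Gaussian-smoothed (σ = 0.8 voxel):
binary marching cubes produces lattice-aligned terracing, and because both
acquisitions are rasterized on the same world lattice, an aligner can
trade true pose against terrace alignment — a systematic rotation bias of
several tenths of a degree.  Anti-aliasing removes the terraces at the
cost of a curvature-dependent volume shrinkage (≈ σ²·κ surface offset), so
volume and inertia computations use the unsmoothed surface (the default).

## Registration

The Kabsch SVD solution (with determinant correction, so reflections are
impossible) is the least-squares core.  ICP iterates
vertex-to-nearest-surface-point correspondence (candidate faces from a
face-centroid k-d tree, exact point–triangle projection) with uniform
deterministic vertex subsampling (default 2000), optional residual
trimming (default off), identity initialization (the paired acquisitions
share a scanner frame), and convergence at RMS change < 1e-4 mm or 100
iterations.  A principal-axes pre-alignment is available behind a flag for
large motions.

### Registration accuracy

After point-to-point convergence, a symmetric point-to-plane Gauss–Newton
stage polishes the pose: residuals are projected on surface normals with
correspondences taken in both directions (source→target and
target→source).  Quantization ripple projects onto the normals with
opposite signs in the two directions and largely cancels.  On
full-resolution phantom pairs this reduces the per-segment rotation error
from ~0.3–0.6° to under 0.15° and translation error (measured at the
segment centroid) to a few hundredths of a millimetre; the global
fiducial alignment lands within ~0.05°.  Both stages are deterministic.

The per-segment superimposition matrix maps the globally aligned second
acquisition onto the first; its inverse is the forward displacement of the
segment (the convention in which "moved 1 mm posterior" reads +1 mm in x),
and that inverse is what the standardization and regression consume.
Centroid-shift norms are identical either way (‖T c − c‖ = ‖T⁻¹c − c‖ for
rigid T).

## Standardized coordinate system

The frame is built from the uniform-density solid enclosed by the
maxillofacial surface: origin at its centre of gravity, axes the
eigenvectors of its inertia tensor.  Mass properties come from the exact
polyhedral integrals of the watertight mesh, with brute-force voxel
summation as the fallback (and as the independent oracle in tests; the two
agree within 1 % on moments and half a voxel on centroids).  Eigenvectors
are assigned one-to-one to the anatomical hint directions (posterior,
left, superior) by maximal |cosine| and signed along them; if the
resulting triad is left-handed the axis with the weakest hint alignment is
flipped.  Near-equal moments (relative gap < 1e-6) are an error: the frame
of a rotationally symmetric solid is not unique.

Displacements conjugate into the SCS (T_m = F T_l F⁻¹, which preserves
rotation angle), and decompose about the segment's first-acquisition
centroid as three translation components plus extrinsic x→y→z Euler angles
(R = R_z(γ)·R_y(β)·R_x(α), α applied first, matching the stated α→β→γ
order about fixed axes; intrinsic vs extrinsic is not specified by the
convention's source, and extrinsic matches the "around the central axis"
phrasing).  |β| = 90° is gimbal-locked and rejected; all angles reported
in degrees on (−180°, 180°], positions in mm.

## Centerline extraction and bifurcation tracking

The medial curve network is extracted on the voxel mask (a
distance-transform formulation of the same medial-axis objective as the
Voronoi-diagram method used interactively in vascular toolkits):

1. Euclidean distance transform D of the lumen; 26-neighbour voxel graph
   with edge length in mm, plus a penalized copy whose edge weights are
   scaled by (1 − D/D_max)⁴ + 0.05 so minimal paths hug the ridge of D.
2. Root at the global D maximum; the first medial path runs to the
   geodesically farthest voxel.  Remaining branch tips are discovered
   iteratively as the voxels farthest (plain geodesic distance) from the
   growing tree, each traced back to the tree along the penalized graph;
   discovery stops when every voxel is within 2 × D_max of the tree,
   which suppresses spur tips.  Deterministic by construction (first-index
   tie-breaks).
3. The voxel tree is split into polylines at nodes of degree ≠ 2; leaf
   polylines shorter than 2 × the junction's inscribed radius are pruned;
   leaf ends that have run into the rounded cap of a tube (inscribed
   radius < 0.9 × the branch radius, estimated from the tip-side half of
   the branch) are trimmed back to where the maximal inscribed sphere
   touches the cap.
4. Polyline interiors are smoothed with a 5-point moving average
   (endpoints fixed; any point smoothed out of the mask reverts).
5. Junction coordinates are sharpened by intersecting the incident branch
   axes: lines are fitted to each incident polyline outside 1.5 local
   radii of the junction and the node moved to their least-squares
   intersection (accepted when within 2.5 radii of the traced point).
   This removes the parent-ward bias of ridge tracing at shallow branching
   angles; phantom junctions land within ~0.5–1.0 mm of truth at full
   resolution.

Bifurcations are labeled vA–vE by globally greedy nearest-template
one-to-one assignment (ties broken in label order) against a labeled
reference — the phantom's ground-truth tree here, a previously labeled
scan in general; missing junctions yield partial labeling with a warning,
not an error.  Shifts are post − pre per label after the post tree has
been mapped by the global alignment, with components reported in either
frame (norms are frame-invariant, checked to 1e-9).

## Statistics

Shift tables hold one row per subject, columns C1…C4, mandible, vA…vE
(non-negative mm).  Summaries are mean, sample SD (n−1 denominator — the
convention that reproduces the published reference values), and max;
reports round half-up to 2 decimals, full precision is kept internally.
The group comparison pools all C1–C4 entries (bones) and all vA–vE entries
(vessels) within each group.  The built-in reference table is the
published six-subject cohort; groups default to its low-motion {2, 3, 6} /
high-motion {1, 4, 5} split.

The regression fits each of the 15 (bifurcation, component) targets by
ordinary least squares on the four vertebral regressors plus intercept —
in-repo via `lstsq` (statsmodels is an independent cross-check in the test
suite, never the implementation).  x₄ is in degrees while x₁–x₃ are in mm;
no standardization is applied, following the source convention.  A fit
with five observations is saturated (residuals ~0) and warns; rank
deficiency is an error.  `predicted_observed_r` pools fitted vs observed
components over all targets into one Pearson correlation.

## Experiment sizes and observed recovery

Problem sizes were chosen so the full suite and the acceptance script each
run in a few minutes on one CPU:

- unit and property tests run on the half-resolution phantom
  (0.86 × 0.86 × 1.0 mm, ≈ 0.7 M voxels; scene generation ≈ 1 s, full
  pipeline ≈ 4 s);
- the end-to-end acceptance checks use one full-resolution pair
  (0.43 × 0.43 × 0.5 mm, ≈ 6.5 M voxels, ≈ 20 s);
- the cohort recovery experiment uses 6 half-resolution subjects sharing
  one anatomy with independent motions and noise; the regression-recovery
  cohort uses 50 subjects with exact (voxel-free) ground truth, since
  nothing about OLS recovery depends on the imaging chain.

Observed at full resolution (across seeds): per-segment rotation recovery
≤ 0.15°, centroid translation ≤ 0.05 mm, bone Dice 0.96–0.99, bifurcation
shift-norm error ≤ ~0.4 mm.  At half resolution the corresponding figures
are roughly 3–5× looser (bifurcation tracking has a noise floor of
~0.5–1 mm there), which is why small-shift columns (vD, vE) of a
half-resolution cohort read slightly high in the mean.

## Known limitations

- The phantom's intensity model is three noiseless classes plus Gaussian
  noise; nothing here validates threshold selection, artifact handling or
  partial-volume behaviour on real CTA.
- The Gaussian-blend deformation is a modeling choice, not measured
  vessel mechanics; passing tests show the pipeline recovers whatever the
  blend produces, not that real arteries deform this way.
- The cohort generator reuses one anatomy across subjects (motions and
  noise vary); anatomical variability is out of scope.
- Lumen radius is constant per branch and preserved under deformation; no
  stenosis, diameter or hemodynamic analysis.
- With six subjects and five parameters the published-style regression has
  one residual degree of freedom per target; the package warns on
  saturated fits, and the 50-subject recovery experiment exists precisely
  because n = 6 cannot validate the model.
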