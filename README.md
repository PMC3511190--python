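# carotidshift

Quantifying carotid-artery (CA) deformation between two CT-angiography
acquisitions of the same patient — the question that decides how much a
preoperative vascular roadmap can be trusted during electromagnetic
catheter navigation for intra-arterial chemotherapy of advanced oral
cancer.  The carotid tree is soft tissue: when the head, neck or jaw move
between imaging and intervention, its bifurcations shift by millimetres to
over a centimetre, and that shift is an error budget line item for any
navigation system.

`carotidshift` implements the full measurement chain on paired
contrast/non-contrast CT volumes, together with a digital neck phantom
whose ground truth is known exactly, so every stage is testable without
patient data:

1. **Segmentation** — bone by thresholding the non-contrast volume; the
   vessel by Boolean subtraction of bone from the thresholded contrast
   volume; individual segments (skull/maxillofacial, C1–C4, mandible, CA)
   isolated by region growing; surfaces by marching cubes.  Quality is
   gated on the Dice coefficient *s* = 2|A∩B| / (|A|+|B|) > 0.95 between
   the two co-registered acquisitions.
2. **Rigid registration** — the second acquisition is superimposed on the
   first via ICP on the maxillofacial (fiducial) surfaces, giving the
   global matrix **T**; each remaining segment is then superimposed
   individually, giving **T**<sub>C1</sub> … **T**<sub>C4</sub>,
   **T**<sub>mandible</sub>, **T**<sub>CA</sub>.  The ICP core is Kabsch
   least squares with vertex-to-surface correspondences and a symmetric
   point-to-plane polish.
3. **Standardized coordinate system (SCS)** — origin at the maxillofacial
   centre of gravity, axes along its principal axes of inertia (signed
   roughly posterior/left/superior), so displacements are comparable
   across patients regardless of how each was positioned in the scanner.
   A displacement **T**<sub>l</sub> measured in the scanner frame (PCS)
   maps by conjugation, **T**<sub>m</sub> = **T**<sub>PCS→SCS</sub>
   **T**<sub>l</sub> **T**<sub>PCS→SCS</sub><sup>−1</sup>, and is reported
   as (Δx′, Δy′, Δz′) in mm plus Euler angles (Δα′, Δβ′, Δγ′) in degrees
   (rotation order α→β→γ about x, y, z).
4. **Bifurcation tracking** — vessel centerlines extracted as the medial
   curves of the lumen mask (distance-transform-penalized shortest paths),
   the five external-carotid bifurcations labeled vA (ICA/ECA), vB
   (lingual), vC (facial), vD (occipital), vE (maxillary origin), and
   their 3D displacements measured in both frames.
5. **Statistics** — per-cohort mean ± SD (max) shift tables, the
   low/high-motion group comparison, and the multiple linear regression

   y<sup>i,j</sup> = b₀ + b₁x₁ + b₂x₂ + b₃x₃ + b₄x₄,  i ∈ {vA…vE}, j ∈ {Δx′, Δy′, Δz′}

   with the four vertebral regressors x₁ = C4Δx′−C2Δx′, x₂ = C4Δy′−C2Δy′,
   x₃ = C4Δz′−C2Δz′, x₄ = C4Δα′−C2Δα′ (one OLS fit per target, 15 fits).

The phantom deforms its carotid tree with a normalized Gaussian-weighted
blend of the bone motions — an explicit instantiation of the assumption
that the rigid bodies around the artery drive its deformation — so every
bifurcation shift has an analytic ground-truth value.

## Worked example

A half-resolution phantom pair with sampled neck motions, analyzed end to
end:

```python
import numpy as np
from carotidshift import (PhantomConfig, generate_scene,
                          sample_admissible_motions, analyze_pair)
from carotidshift.pipeline import truth_relative_transforms

pre = generate_scene(PhantomConfig.coarse(seed=0))
motions, post = sample_admissible_motions(pre, np.random.default_rng(0),
                                          motion_scale=1.0,
                                          amplitude_jitter=0.2,
                                          skull_motion=True)
result = analyze_pair(pre, post)
rel = truth_relative_transforms(motions)  # injected motion, skull removed
print("skull-relative centroid shift (mm):")
for name in ("C1", "C2", "C3", "C4", "mandible"):
    c = pre.bone_centroids[name]
    injected = np.linalg.norm(rel[name].apply(c) - c)
    print(f"  {name:9s} injected {injected:5.2f}   measured "
          f"{result.centroid_shifts[name]:5.2f}   Dice {result.dice_reports[name].s:.3f}")
print("bifurcation shifts (mm, standardized frame):")
for s in result.shifts_scs:
    print(f"  {s.label}: |d| = {s.norm:4.2f}   (dx', dy', dz') = "
          f"({s.delta[0]:+.2f}, {s.delta[1]:+.2f}, {s.delta[2]:+.2f})")
```

which reports the injected vs measured centroid shift of each mobile bone
(mm), its Dice QA value, and the tracked bifurcation displacements:

```
skull-relative centroid shift (mm):
  C1        injected  1.07   measured  1.05   Dice 0.954
  C2        injected  1.42   measured  1.40   Dice 0.959
  C3        injected  2.84   measured  2.83   Dice 0.949
  C4        injected  4.14   measured  4.10   Dice 0.952
  mandible  injected  0.94   measured  0.95   Dice 0.961
bifurcation shifts (mm, standardized frame):
  vA: |d| = 2.40   (dx', dy', dz') = (+1.62, -0.48, -1.71)
  vB: |d| = 2.54   (dx', dy', dz') = (+2.40, -0.84, +0.01)
  vC: |d| = 0.76   (dx', dy', dz') = (+0.68, +0.24, +0.27)
  vD: |d| = 1.32   (dx', dy', dz') = (+0.89, +0.92, +0.35)
  vE: |d| = 1.48   (dx', dy', dz') = (+0.75, +1.02, +0.76)
```

The global head motion (here ~1° / 1 mm on the fiducial) has been removed
by the maxillofacial alignment; each vertebra's residual motion is
recovered to a few hundredths of a millimetre, and the bifurcation shifts
follow the C4-dominated motion gradient down the column.  At the default
CT resolution (0.43 × 0.43 × 0.5 mm) recovery is several times tighter
(see `docs/methods.md`).

The built-in six-subject reference shift table reproduces its published
summary statistics:

```
$ carotidshift reproduce-table1
per-column mean / sample SD / max (mm):
          mean    sd    max
C1        1.02  0.90   2.19
C2        2.18  1.81   4.68
...
vE        2.47  1.32   4.59

cervical C1-C4 mean shift: group A 1.17 mm, group B 5.51 mm
bifurcation vA-vE mean shift: group A 2.51 mm, group B 5.84 mm
```

Other entry points: `carotidshift simulate --seed 1 --out DIR` writes a
phantom scene pair (binary STL surfaces, MetaImage volumes, ground-truth
JSON); `carotidshift recover --subjects 6 --seed 0 --out DIR` runs the
phantom-cohort recovery experiment and writes its CSV/JSON report.

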