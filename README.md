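# vitreoseg

Fully automated segmentation of the **posterior vitreous boundary** in 3D
macular OCT volumes, and unsupervised phenotyping of **vitreomacular
adhesion (VMA)** from the resulting en-face ILM–vitreous distance maps.

The state of the vitreomacular interface is a candidate prognostic
biomarker for anti-VEGF therapy in exudative macular disease, but grading
it by hand in 49-B-scan OCT cubes does not scale to trial-sized image sets.
`vitreoseg` implements an automated pipeline for this task and a synthetic
phantom generator so that every stage can be validated without clinical
data. It is aimed at ophthalmic image-analysis researchers and at anyone
who needs a tested, self-contained implementation of graph-based optimal
surface extraction with learned rotation-invariant features.

## Method

Segmentation runs in four stages:

1. **Rotation-invariant eigenfeatures.** For a 21×21 circular patch *I*,
   masked image moments M̂_pq = Σ_x Σ_y x^p y^q I[x,y] mask[x,y] give the
   normalized central moments µ′_20, µ′_11, µ′_02 and the local orientation
   φ(I) = ½·atan2(2µ′_11, µ′_20 − µ′_02) — the angle of the patch's major
   axis. Training patches are rotated into this canonical frame and the
   first 20 PCA eigenvectors become convolution kernels; at every voxel the
   kernel is rotated by the local orientation before application, so the
   response is invariant to the orientation of the underlying structure.
2. **Voxelwise region prediction.** A random forest maps the 20 features to
   probabilities over 5 anatomical regions (vitreous, vitreous cortex,
   cortex–ILM gap, retina, sub-RPE). The cortex is assumed ≥ 3 voxels
   thick and the 20 voxels exterior to the annotated boundary are excluded
   from training.
3. **Graph-based surface extraction.** The four boundary surfaces
   (cortex top/bottom, ILM, RPE) minimize a region-cost objective — the
   summed probability mass misassigned by the exterior/interior partition
   each surface induces — under hard smoothness and minimum-separation
   constraints, solved to global optimality as a minimum-cost closed set
   via max-flow (an int64 Dinic solver compiled with numba). Columns whose
   peak cortex probability stays below a threshold are reported as
   "vitreous out of range" (complete posterior vitreous detachment, PVD).
4. **Auto-context refinement.** Signed axial distances to the current
   surfaces and probability samples at fixed axial offsets are appended to
   the features, and a fresh classifier is trained; two such iterations are
   the default.

For each eye, the ILM–vitreous distance map (µm, per A-scan) is summarized
as a histogram; k-means over these histograms (k = 2–4) separates non-VMA
eyes (attached *or* complete PVD) from VMA phenotypes of increasing
separation. Cluster-level statistics (one-way ANOVA; OLS of visual-acuity
change adjusted for baseline acuity) and a simulation of the
baseline-confound attenuation mechanism round out the analysis layer.

## Worked example

```python
import numpy as np
from vitreoseg import (PhantomSpec, generate_phantom, PipelineConfig,
                       train_models, run_autocontext,
                       evaluate_against_reference, distance_map)

# ground-truthed synthetic cohort: train on 4 eyes, test on 1
classes = ["attached", "shallow_vma", "steep_vma", "complete_pvd"]
train = [generate_phantom(PhantomSpec(grid_shape=(12, 48, 96), vma_class=c,
                                      noise_level=0.3, seed=i))
         for i, c in enumerate(classes)]
config = PipelineConfig(n_patches=3000, n_trees=30, per_class_cap=4000)
bank, cascade = train_models([(v, t.surfaces) for v, t in train], config)

vol, truth = generate_phantom(PhantomSpec(grid_shape=(12, 48, 96),
                                          vma_class="steep_vma",
                                          noise_level=0.3, seed=99))
trace = run_autocontext(vol, bank, cascade)
summary = evaluate_against_reference(trace.final_surfaces, truth.surfaces,
                                     vol.axial_spacing)
d = distance_map(trace.final_surfaces, vol.axial_spacing)
print(f"ILM MAE      : {summary.surface_mae['ilm']:.2f} voxels")
print(f"boundary MAE : {summary.surface_mae['vit_bottom']:.2f} voxels")
print(f"mean gap     : {d.mean_defined_um:.1f} um "
      f"(missing fraction {d.missing_fraction:.2f})")
```

Typical output:

```
ILM MAE      : 0.11 voxels
boundary MAE : 1.15 voxels
mean gap     : 110.1 um (missing fraction 0.07)
```

The ILM and the posterior vitreous boundary of the held-out eye are
recovered to about a voxel on average; the mean ILM–vitreous gap of this
steep-VMA eye is ~110 µm, with 7% of A-scans flagged as out-of-range
(boundary above the scanned depth at the volume periphery).

The same stages are scriptable from the shell:

```bash
vitreoseg phantom --out-dir data --n-eyes 6 --seed 1
vitreoseg train-features --volumes data/eye0000.tiff ... --out bank.npz
vitreoseg train-model --volumes ... --truths ... --bank bank.npz --out cascade.joblib
vitreoseg segment --volumes ... --bank bank.npz --model cascade.joblib --out-dir out
vitreoseg cluster --surfaces out/eye0000/surfaces.tsv ... --k 2 --out clusters.json
```

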