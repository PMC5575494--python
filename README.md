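# agree3d

Pairwise 3D contour-agreement analysis for organ-segmentation studies,
with a seeded synthetic cohort generator so the whole pipeline can be
exercised end-to-end without any patient data.

The package implements the evaluation design used in interobserver /
semiautomated-segmentation studies on 3D ultrasound: closed triangle-mesh
contours of one organ per image are compared pairwise with four metrics,
stratified by image-quality rating, and tested for group differences.

* **DC** — Euclidean distance between volume centroids (mm).
* **DSC** — Dice similarity coefficient `2|A∩B| / (|A|+|B|)` on a shared
  isotropic voxel grid.
* **MSSD** — directed mean, over contour A's vertices, of the distance to
  the nearest vertex of B (mm).
* **UM95** — smallest uniform margin expanding A so that ≥ 95 % of B's
  volume is covered (mm), via the nearest-rank quantile of A's distance
  field over B's voxels.

All coordinates are millimetres in a patient frame with +x Left,
+y Anterior, +z Superior.

## Layout

| module | contents |
| --- | --- |
| `agree3d.geometry` | watertight `SurfaceContour`, `VoxelMask`, volume / centroid, parity-raycast voxelization, Euclidean distance fields, uniform margin expansion |
| `agree3d.metrics` | the four metrics, per-vertex deviation maps, a cached `PairwiseEvaluator` for many pairs on one grid |
| `agree3d.pipeline` | quality-rating rules (two sessions, round-half-up mean, zero-rating exclusion), ordered pair enumeration (n·(n−1) manual pairs, ags × manual cross product), failure ledger, median [IQR] summaries, Wilcoxon rank-sum tests with Bonferroni correction |
| `agree3d.synthetic` | uterus-like shape generator (superellipsoid body + cervical capsule, anteverted), smooth spherical-harmonic observer perturbations, quality-dependent semiautomated-contour error model with failures and protrusion artifacts, seeded cohort assembly, MSSD calibration |
| `agree3d.meshfiles` / `agree3d.manifest` | PLY (ascii + binary) and STL I/O with orientation repair, cohort manifest / ratings-table files |
| `agree3d.reporting` / `agree3d.cli` | run config, provenance, summary CSVs, boxplots, the `agree3d` command |

## CLI

```bash
# generate a synthetic cohort (35 retained images, 4 observers by default)
agree3d simulate --seed 1 --out runs/cohort

# all pairwise agreement records (12 manual + up to 16 ags-vs-manual per image)
agree3d evaluate --manifest runs/cohort/manifest.json --spacing 1.0 \
    --coverage 0.95 --out runs/eval

# median [IQR] tables, rank-sum statistics, full report with boxplots
agree3d summarize --records runs/eval/records.csv --out runs/summary
agree3d stats     --records runs/eval/records.csv --alpha 0.05 --out runs/stats
agree3d report    --records runs/eval/records.csv \
    --manifest runs/cohort/manifest.json --out runs/report
```

Exit codes: 0 success, 2 validation error, 3 I/O error.  Every run writes
a `provenance.json` with library versions and the statistical/geometric
conventions used.  `report` additionally writes per-image interobserver
deviation heatmaps as PLY files with a `deviation_mm` vertex property
(display scale conventionally clamped at 10 mm).

## Conventions worth knowing

* Meshes must be closed, consistently outward-oriented 2-manifolds;
  readers repair winding or fail loudly with a defect report.
* A voxel is occupied iff its centre is inside the mesh (unbiased volume
  estimator); default spacing 1 mm, configurable everywhere.
* MSSD is vertex-to-vertex by definition; an exact point-to-triangle
  variant is available behind `point_to_surface=True` for sensitivity
  analysis.
* MSSD and UM95 are directed (recorded per ordered pair); DC and DSC are
  symmetric.  Summaries pool pairwise records within a group by default;
  per-image aggregation is available (`aggregate="per_image"`), and is
  what the statistical null checks use since pooled pairwise records are
  not independent samples.
* Ratings: two sessions on a 0–3 scale; any 0 excludes the image,
  otherwise the final rating is the round-half-up mean.
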