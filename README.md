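# mitomorph3d

Quantitative 3D morphometry of mitochondrial networks in labeled electron
microscopy volumes of skeletal muscle.

Serial block face SEM produces anisotropic image stacks (here ~10 × 10 nm
in-plane, 30 nm section thickness) in which individual mitochondria are
manually traced as integer-labeled segmentation volumes. This package turns
such label stacks — or synthetic phantoms standing in for them — into
per-organelle and population-level morphology numbers:

- **Shape complexity.** Each organelle is meshed (marching cubes on its
  smoothed binary mask, anisotropy-aware) and scored by the mitochondrial
  complexity index, **MCI = SA³ / (16 π² V²)** — a scale-invariant 3D
  analogue of form factor, minimised by the sphere at 9/(4π) ≈ 0.716 and
  unbounded above as branching grows. Sphericity,
  π^⅓ (6V)^⅔ / SA, is computed alongside
  (MCI · sphericity³ = 9/(4π) exactly).
- **Branching anisotropy.** The mitochondrial branching index
  **MBI = TBI / LBI**, with TBI = myofibrils bridged + 1 and
  LBI = 2·sarcomeres + half-sarcomeres + z-bands + 1, computed as an exact
  rational from annotated counts, or approximately from centerline skeleton
  extents; organelles classify as transverse (> 1), equal (= 1) or
  longitudinal (< 1), plus a full-sarcomere-spanning flag.
- **Nanotunnels.** Thin double-membrane projections are detected on the
  skeleton as sub-paths whose external diameter (2 × Euclidean distance
  transform) stays ≤ 250 nm over ≥ 50 nm, classified free-ended vs
  connecting, and measured: length, diameter extremes, and estimated matrix
  lumen = external minimum − 24 nm of membrane.
- **Population analytics.** "Simple"/"complex" (MCI) and "small"/"large"
  (volume) classes cut at the 10th/90th percentiles of the pooled control
  population; coefficients of variation within cells, between cells and
  between persons; volume density over two sarcomeres; skewness/kurtosis
  and cumulative distributions.
- **Inference.** Exact/asymptotic Mann-Whitney tests, chi-square tests on
  branching-class tables, and a nested random-intercept variance
  decomposition (mitochondria in cells in persons) fitted by REML on
  log-transformed metrics.
- **Disease signature.** A from-scratch NIPALS PLS-DA on eight
  per-individual features with VIP ranking (mean squared VIP = 1), nearest-
  centroid prediction, and explained-variance accounting.
- **Synthetic truth.** Voxel phantoms (spheres, capsules, tube networks,
  nanotunnel dumbbells), sarcomere-registered network volumes, and
  hierarchical lognormal cohorts with known ground truth make every module
  testable without any image data.

## Worked example

```python
from mitomorph3d import (ShapeSpec, voxelize, mesh_from_mask,
                         mesh_surface_area, mesh_volume, mci, detect_in_mask)

# a 500 nm-radius sphere rasterised at 10 x 10 x 30 nm
vol, truth = voxelize(ShapeSpec("sphere", {"radius": 500.0}))
mesh = mesh_from_mask(vol.labels > 0, vol.voxel_size)
print(mci(mesh_surface_area(mesh), mesh_volume(mesh)))   # 0.7188 (floor 0.7162)

# two 600 nm bodies joined by a 100 nm x 800 nm tube
vol, truth = voxelize(ShapeSpec("nanotunnel_dumbbell",
    {"body_radius": 300.0, "tube_radius": 50.0, "tube_length": 800.0}))
nt, = detect_in_mask(vol.labels > 0, vol.voxel_size)
print(nt.end_status, round(nt.length_nm), round(nt.lumen_min_nm))
# connecting 780 93
```

The sphere's meshed MCI lands within 0.4% of the analytic floor; the
dumbbell yields exactly one connecting nanotunnel whose measured length
(780 nm) is within 2.5% of the constructed 800 nm tube, and whose lumen
estimate follows from the −24 nm membrane correction.

Longer narrative scripts live in `examples/` (shape complexity, branching
anisotropy, nanotunnels, population statistics + variance components, and
the PLS-DA signature); each prints the numbers it computes and what they
mean. A thin CLI wraps the same library:

```bash
mitomorph3d simulate --preset control --seed 1 --out stack.tif --truth truth.csv
mitomorph3d metrics --volume stack.tif --voxel 10,10,30 --out metrics.csv
mitomorph3d popstats --metrics metrics.csv --out summary.csv
```

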