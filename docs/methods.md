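# Methods

This note records the models and numerical choices behind mitomorph3d, in
the spirit of a methods appendix: what each quantity is, which knobs matter,
and where the approximations live.

## Coordinate conventions and units

Label grids are stored `(z, y, x)` with z the section/stack axis; because
acquisition is transverse to the muscle fiber, z is also the fiber's
longitudinal axis (the axis tag on `LabeledVolume` can override this). All
internal lengths are nanometres; metric tables convert to µm³/µm² only at
the CSV boundary. The reference voxel size is (10, 10, 30) nm — 10 nm
in-plane pixels, 30 nm section thickness — and every geometric routine
(distance transforms, mesh spacing, arc lengths) honours that anisotropy.

## Organelle extraction

Connected components are taken per label with 26-connectivity: diagonal
voxel contacts merge, which mirrors how a continuous outer membrane is
traced through section-to-section jogs. Components touching the grid
boundary are flagged and, by default, excluded from population statistics
(a truncated organelle biases volume and MCI downward). Organelles below 20
voxels (config `min_reliable_voxels`) are retained but flagged: at 30 nm
section pitch such objects are only 1–3 sections thick and their meshes are
unstable.

## Surface meshing and the complexity index

SA and V come from a closed triangle mesh of the 0.5-level marching-cubes
isosurface of the organelle's binary mask. Two numerical choices matter:

- **Gaussian pre-filter, σ = 2.5 × finest voxel pitch (25 nm at
  reference).** Marching cubes applied to a raw binary field produces a
  faceted surface whose area overestimates a smooth surface badly (+16.6%
  for a 500 nm sphere at the reference anisotropy, +8.7% even for isotropic
  voxels). Because MCI scales as SA³/V², a 2% headline accuracy requires
  sub-percent SA accuracy. A Gaussian pre-filter of the indicator field at
  σ = 25 nm — below the section pitch, so no real feature of a traced
  organelle is lost — brings the meshed sphere to −0.4% SA / −0.8% V and
  MCI to within 0.5% of the analytic 9/(4π). The scale is config-exposed
  (`mesh_smoothing_sigma_nm`; 0 meshes the raw binary field). It was
  calibrated once against analytic sphere/capsule phantoms.
- **4× upsampling of sub-6-voxel objects.** The trilinear isosurface of a
  single voxel is an octahedron enclosing only ~17% of the voxel volume;
  nearest-neighbour upsampling before meshing restores the cuboid geometry
  (single reference voxel meshes to 2750 nm³ vs 3000 nm³ true, −8%). If
  smoothing would erase a small object entirely (peak field ≤ 0.5), the
  raw binary field is meshed instead.

MCI uses the mesh volume, not the voxel count, so that SA and V describe
the same surface; the voxel-count volume is retained as a cross-check and a
>10% disagreement is flagged.

**Resolution limit.** At 30 nm section pitch, the binary mask of a tube
thinner than ~12 sections across carries an irreducible few-percent volume
discretisation error — voxel counting itself errs by ±3–5% for 100–180 nm
radius tubes, depending on how the radius lands on the section lattice. The
2% meshed-MCI guarantee therefore applies to organelle-scale bodies
(diameter ≳ 400 nm); thin protrusions are measured by the distance-transform
machinery below, which does not require percent-level SA accuracy. Halving
the voxel pitch shrinks all meshing errors monotonically on analytic
phantoms.

MCI is exactly scale invariant by construction — mci(c²SA, c³V) ≡ mci(SA, V)
— and bounded below by the sphere value 9/(4π) ≈ 0.7162 (isoperimetric
inequality); the identity MCI · sphericity³ = 9/(4π) ties it to sphericity.
The sphere does *not* score 1 under this definition; no renormalisation is
applied.

## Branching (MBI)

Annotation mode is the faithful method: integer counts of myofibrils
bridged, sarcomeres, half-sarcomeres and z-band crossings, combined as
TBI = m + 1, LBI = 2s + h + z + 1, MBI = TBI/LBI kept as an exact
`Fraction`, so the three-way classification (transverse > 1, equal = 1,
longitudinal < 1) never suffers float ties. The degenerate all-zero count
scores MBI = 1.

Geometric mode approximates those counts from a centerline skeleton and is
flagged `approximate`:

- *Myofibrils bridged* = ⌊max transverse span / w⌋ with nominal myofibril
  width w = 1.0 µm. The total span is used (a straight rod spanning 3w
  bridges 3 myofibrils); no per-side bookkeeping is attempted because voxel
  labels carry no myofibril boundaries.
- *Longitudinal features* are counted once each from the longitudinal span:
  ⌊L/s⌋ sarcomeres (s = 2.0 µm nominal) plus one half-sarcomere if the
  remainder reaches s/2; z-band crossings beyond the home plane that are
  not already implied by counted (half-)sarcomeres are added only when
  z-band plane positions are supplied.
- *Spans* prefer the source-mask extent over skeleton-node extent: 3D
  thinning retracts skeleton ends by roughly the tube's voxel-space radius,
  which along a 30 nm axis is 3× the physical radius — node extents would
  systematically under-count. Skeletons built directly from points (no
  mask) use node extents.

"Spans a full sarcomere" is inclusive: extent ≥ s.

A practical note on thinning: scikit-image's 3D skeletonization can delete
a perfectly symmetric even-width tube entirely (a tie-break artefact) and
erases objects that touch the array border. The skeletonizer therefore pads
the mask and, when thinning returns nothing, retries on a one-voxel
asymmetrically eroded mask, finally falling back to the deepest single
voxel.

## Nanotunnels

The external diameter profile along the skeleton is 2 × the anisotropic
Euclidean distance transform at each node (a half-voxel-scale overestimate
for thin tubes, well inside the one-voxel-diagonal measurement tolerance).
Detection finds maximal skeleton sub-paths with diameter ≤ `d_max` sustained
over ≥ `l_min`. The defaults d_max = 250 nm and l_min = 50 nm are
*operational* thresholds chosen to bracket observed nanotunnel dimensions
(external diameters ~26–204 nm, lengths ~65 nm–2 µm); they are config
values, and an annotation mode (`measure_nanotunnel`) measures between
human-supplied endpoints instead.

Each terminus attaching to a thick (body) region is clipped where the
centerline exits the body's maximal inscribed sphere (centred at the body's
deepest node). A naive diameter-threshold clip overshoots into the body by
~(d_max − d_tube)/2 per end — +31% length error on an 800 nm dumbbell tube —
while inscribed-sphere clipping measures it to within 2.5%. Tunnels attached
at both ends are `connecting`; otherwise `free_ended`.

The minimal matrix lumen is d_ext_min − 24 nm: per side, 8 nm intermembrane
space plus 2 nm each of outer and inner membrane, twice. The constant is
config (`membrane_correction_nm`); negative estimates clamp to 0 with a
flag. Nucleoid passability uses lumen > 110 nm, the nominal nucleoid
diameter. Frequencies are reported per 100 mitochondria.

## Population statistics

Percentile thresholds use linear interpolation between order statistics
(numpy's default, the "type 7" rule). With strict inequalities for class
membership, a pooled control population of distinct values whose size is a
multiple of ten puts exactly 10% of organelles below q10 — the definitional
control baseline for the "simple" class. Ties at a threshold fall into the
middle class, keeping the baseline ≤ 10%.

CVs are computed on the natural scale at three levels: per-cell SD/mean,
per-person CV of cell means, and CV of person means; single-organelle cells
are excluded with a warning. Kurtosis defaults to the raw (Pearson,
normal = 3) convention with an excess option, since either convention is
seen in the literature. Volume density is 100 × Σ organelle volume / fiber
volume over two sarcomeres; a mitochondrial total exceeding the fiber
volume is rejected as a segmentation inconsistency.

## Inference

Mann-Whitney U is exact by full enumeration of group assignments for
combined n ≤ 20 (ties handled via midranks; two-sided p is the probability
of a |U − n₁n₂/2| deviation at least as large), and otherwise uses the
tie-corrected normal approximation with continuity correction. The
chi-square test on class-proportion tables is Pearson's, without Yates
correction, via scipy.

The variance decomposition fits y = Xβ + a_person + b_cell(person) + ε with
random intercepts by REML, directly minimising the restricted negative
log-likelihood (Nelder-Mead on log-variances; per-person covariance blocks
are small and solved by Cholesky). Method-of-moments estimates provide
starting values and the fallback. Group labels enter as fixed effects with
treatment coding. With one cell per subject the cell component is
confounded with the person component; it is pinned to zero and reported as
NaN with a flag. Log transforms use the natural log — metric distributions
here are strongly right-skewed, and the SD ratios are base-independent. The
implementation agrees with statsmodels MixedLM to four decimals on shared
test problems and recovers simulated SD triples (0.28 person, 0.14 cell,
0.81 within at 8 × 3 × 50 sampling) to within a few percent on average.

## PLS-DA signature

Features per individual: percent simple, complex, small, large; median MCI
and volume; volume density; nanotunnels per 100. X is autoscaled
(center + unit variance; config to disable), Y is the one-hot group matrix,
and components come from NIPALS PLS2 — deterministic given row order, no
randomness. Explained X/Y variance per component is the deflated sum of
squares fraction. VIP_j = √(p · Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ); mean squared VIP is
1 exactly, and features above 1 are flagged discriminant. Prediction
projects new rows through W(PᵀW)⁻¹ and calls the nearest group centroid in
score space. Zero-variance columns are dropped with a warning; if X carries
no covariance with the response (e.g. perfectly confounded labels), the
component falls back to the dominant X direction with zero response
loading rather than dividing by zero. The explained-variance accounting is
documented here and is not claimed to match any particular external PLS
implementation bit for bit.

## Synthetic data

The generators define the conditions under which the package is validated:

- `voxelize` rasterises unions of capsule segments on a lattice centred on
  the shape (corner-anchored lattices introduce a half-voxel erosion bias,
  measured at −7% volume on a capsule). Analytic SA/V truths attach for
  spheres and capsules; tube geometry for the dumbbell and blind-protrusion
  nanotunnel phantoms.
- `generate_fiber_volume` seeds organelles on a parity checkerboard of
  (column, column, z-band plane) cells — guaranteeing ≥ 1 background voxel
  between organelles, the synthetic analogue of resolving distinct outer
  membranes. Classes follow a configurable transverse/equal/longitudinal
  mix (defaults 0.404/0.506/0.091, a healthy-muscle-like anisotropy);
  transverse capsules bridge 1–2 myofibril widths (all along one in-plane
  axis, since perpendicular 2-width rods in diagonal cells would touch),
  longitudinal capsules span a half or full sarcomere (full spanners only
  at the top plane, where no rods lie above), and a configurable fraction
  of compact organelles becomes a two-body dumbbell with a 300 nm
  connecting tunnel. Per-organelle truth records class, counts and
  nanotunnel geometry.
- `generate_cohort` draws hierarchical lognormal volumes (natural-log SDs
  0.81 within-cell, 0.14 between-cell, 0.28 between-person around a
  0.25 µm³ median) and complexities (floor + lognormal with SDs
  0.68/0.26/0.43 around floor + 1.3), for 8 control and 6 disease subjects,
  3 cells × 50 mitochondria each. The disease group resamples a mixture
  fraction (m − 0.1)/0.9 of its complexity values from the control
  below-q10 pool so its pooled simple mass hits the target m (default
  0.46; targets below the 10% baseline are infeasible and rejected), and
  draws Poisson nanotunnel counts at 38 vs 2.1 per 100. By default *only*
  the simple fraction and the nanotunnel rate differ between groups, which
  is what makes the VIP top-2 recovery test meaningful.

What the phantoms do not emulate: real tracing noise and inter-rater
variability, curved/branched organelle topologies beyond capsule unions,
membrane appearance (only label masks are produced), myofibril boundaries
(geometric MBI mode is validated against generator truth, not against human
counting), and any correlation structure between features beyond the
engineered group differences. Passing tests therefore demonstrate that the
algorithms recover known geometric and statistical truth under the stated
acquisition geometry — not that they reproduce any particular biological
dataset.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes chosen as the
smallest that exercise each property cleanly: phantom grids of a few
hundred voxels per side, fiber phantoms of 9–36 organelles, cohorts of
8 × 3 × 50 draws, 20 REML replicates and 50–100 PLS-DA seeds. Every
stochastic path takes an explicit seed; identical seeds reproduce volumes,
cohorts and fits bit for bit.

## Known limitations

- Skeleton-based nanotunnel detection assumes tubes are resolvable by the
  distance transform; tunnels thinner than ~2 sections in z are at the
  mercy of the thinning pass.
- Geometric MBI mode cannot see myofibril boundaries or z-bands unless
  given their positions; without them it is extent-based and flagged
  approximate.
- The inscribed-sphere clip of nanotunnel ends is exact for spherical
  bodies and approximate for elongated ones.
- MCI for sub-400 nm organelles inherits the mask discretisation error
  discussed above; such organelles are flagged rather than suppressed.
- PLS-DA on 14 individuals is an illustration of the signature machinery;
  no cross-validated generalisation claim is made at that sample size.
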