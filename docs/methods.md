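# Methods

## The detection model

The detector treats mechanical damage as a *local curvature anomaly* on an
otherwise smoothly convex produce surface. Two complementary curvature
descriptors are computed per point from its k-nearest-neighbour patch:

- **Surface variation** κ = λ₀/(λ₀ + λ₁ + λ₂), from the eigenvalues
  λ₀ ≤ λ₁ ≤ λ₂ of the neighbourhood covariance (formed over the k
  neighbours, centred at their centroid, with 1/k weights). κ is bounded
  in [0, ⅓], zero on exact planes, and — unlike principal curvatures —
  responds to any three-dimensional spread of the patch, which makes it
  robust on the torn edges and multi-layer fractures where a single
  height-field model breaks down. It drives the primary threshold.
- **Principal curvatures and shape parameter.** A quadric z = ax² + bxy +
  cy² is fitted by least squares in a local frame and the principal
  curvatures k₁ ≥ k₂ are the eigenvalues of the second-fundamental-form
  matrix [[2a, b], [b, 2c]] at the origin, giving the scale-free shape
  parameter S = ½ − (1/π)·arctan[(k₁+k₂)/(k₁−k₂)]. S classifies local
  shape (convex cap → 0, concave cup → 1, saddle/plane → ½) and feeds the
  optional second stage.

### Local frame and sign conventions

The quadric's frame sits at the query point itself (not the neighbourhood
centroid): the model has no constant or linear term, so it is exact only at
a point lying on the surface with vanishing gradient, and anchoring it at
the query point preserves exact polynomial reproduction (a patch sampled
from z = x² recovers a = 1 to machine precision). The frame's +z axis is
the covariance normal oriented *along the viewing direction* (away from the
sensor): with that convention a surface bulging toward the sensor has
positive principal curvatures (a sphere of radius R seen from outside gives
k₁ ≈ k₂ ≈ +1/R, S ≈ 0) and depressions get S near 1. The per-point
`normal` output is always oriented toward the viewpoint (default: a sensor
on +z, 10 m out). The tangent axes are the remaining covariance
eigenvectors, ordered by eigenvalue, with deterministic signs
(largest-magnitude component positive, right-handed completion).

### Numerical choices

- Eigen-solves use symmetric routines; covariance eigenvalues in
  (−10⁻¹², 0) are clamped to 0.
- Coincident-point neighbourhoods (λ sum = 0) define κ = 0.
- Umbilic degeneracy of S (k₁ ≈ k₂, |k₁−k₂| ≤ 10⁻¹²): the arctan limit is
  taken — 0 if k₁+k₂ > ε, 1 if < −ε, ½ otherwise.
- Rank-deficient quadric normal equations (determinant below 10⁻¹² on the
  trace scale) raise a degenerate-fit error; in the whole-cloud field such
  points keep κ but are flagged `s_defined = False`, never qualify as
  feature points, and never block one.
- k-NN ties are broken toward the lower point index, making every
  neighbourhood — and hence the whole pipeline — deterministic.
- The voxel grid is anchored at the cloud's minimum corner (floor
  convention on boundaries), so output is translation-consistent within a
  run and sorted by voxel index.
- All standard deviations are population (÷n) statistics.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| filter.neighbor_count | 50 | – | neighbours averaged for the outlier statistic |
| filter.sigma_mult | 1.0 | – | half-width of the acceptance band in σ |
| cluster.tolerance_r | 0.005 | m | Euclidean clustering link distance |
| cluster.min_cluster_size | 100 | pts | discard smaller clusters |
| voxel.voxel_size | 0.001 | m | downsampling cube edge |
| curvature_k | 50 | – | neighbourhood size for κ, quadric and S |
| defect.kappa_threshold | 0.08 | – | stage-one curvature cut |
| defect.region_tolerance | 0.008 | m | candidate grouping distance |
| defect.min_region_points | 10 | pts | minimum region (≈10 mm² at 1 mm voxels) |
| defect.elongation_cutoff | 3.6 | – | crack if in-plane axis ratio ≥ cutoff |
| defect.depth_cutoff_mm | 5.0 | mm | crack if mean depth ≥ cutoff |

The curvature threshold 0.08 is the calibrated split between intact
surface (body and leaf-stem κ stay below ~0.07) and damaged-edge
curvature; an Otsu split of the κ histogram is available behind
`auto_threshold` as an automatic alternative. The sigma band at m = 1 is
deliberately aggressive: it trims both sparse outliers and the sparse
support-plane remnant before clustering. Region grouping at 8 mm keeps a
dent's rim ring connected even where the threshold crossing is
intermittent; the elongation cutoff 3.6 sits in the measured gap between
round dent footprints and narrow crack strips on benchmark samples, and
the depth criterion catches deep narrow fissures whose footprint alone is
ambiguous. All parameters live in one YAML-loadable config (unknown keys
rejected) with CLI overrides.

### Two-stage extraction design

Stage one thresholds κ and bars *open-boundary* points, identified by the
tangent-plane angular-gap criterion (a point whose projected neighbours
leave a sector wider than 2 rad empty sits on an open rim). A
centroid-offset rule was evaluated for this job and rejected: it cannot
distinguish the open rim of a single-view patch from a steep interior
defect wall, and flagged the majority of true rim candidates on deep
dents.

Stage two derives a threshold S* = min S over the feature points (points
whose S strictly exceeds that of all k neighbours) and, when enabled,
keeps regions in which at least `region_validation_frac` of points reach
S*. It is applied at region level rather than pointwise because the
second segmentation exists to eliminate falsely segmented *areas*;
pointwise intersection instead carves true regions down to their concave
cores. The stage ships disabled by default: measured across generated
scenes, S* is an unstable extreme statistic (any local S maximum on a
smooth noisy surface is a concave noise dimple, so S* lands anywhere
between ~0.5 and ~0.85), and the boundary bar already removes the rim
false positives it targets. The machinery remains available and tested
for data where stalk or rim interference survives stage one.

### Region descriptors

Each region's *depth* is the mean signed offset of its points from a full
quadratic reference surface fitted to the non-candidate points within
twice the region radius, in the PCA frame of that surrounding ring; its
*elongation* is the axis ratio of the region footprint projected into the
ring's tangent plane. The in-plane projection matters: a deep crack's
wall points would otherwise inflate the minor axis of a 3D covariance and
mask the narrow footprint. The reference surface necessarily dips toward
the defect (the ring includes displaced but sub-threshold points), so
measured depths understate true indentation depth; the classifier cutoffs
are calibrated on the measured, not the physical, scale. Area is
`points × voxel_size²`, valid because the analyzed cloud is
voxel-downsampled, so each surviving point stands for about one voxel
footprint of surface.

## The synthetic scene generator

The generator emulates a single-view depth scan of a produce head on a
table:

- **Body**: superellipsoid with semi-axes ~8.5 cm and exponent 2.0
  (round-headed) or ~9.5/5.5 cm and 2.6 (flat-headed), sampled at 16,000
  points over the sensor-facing hemisphere — matching a typical single
  frame of a real scan at 0.4 m range.
- **Leaf stems**: six raised-cosine ridges (amplitude 2.5 mm) radiating
  from the pole; they are the main benign curvature interference.
- **Dents**: flat-bottomed depressions with a ~1 mm sigmoid torn edge and
  a lightly rumpled interior, their walls explicitly sampled at body
  density. Radial displacement alone would leave a wall parallel to the
  sampling rays and hence invisible — an artifact no physical camera has.
  Default 10 mm radius, 3 mm depth (a shallow dent near the detection
  floor); benchmark scenes draw 8–14 mm depths with a 10% shallow (2–4 mm)
  minority, emulating a damage population in which a small fraction sits
  below any curvature threshold.
- **Cracks**: inward Gaussian trenches (cross-section σ = width/3, cosine
  length taper); default 40 × 4 mm, 10 mm deep.
- **Clutter**: a support-plane annulus (3,000 points), 50 uniform far
  outliers, and 0.3 mm isotropic Gaussian sensor noise.

Ground-truth labels mark the perceptible depression (commanded
displacement above a quarter of the defect depth), stems, background and
outliers. The benchmark suite emits dent/crack/intact scenes at a 3:3:2
ratio over both body varieties, all seeds derived from one master seed.

**What the generator does not model** — and what passing benchmarks
therefore cannot certify: real leaf texture and wrinkling, specular and
edge artifacts of structured-light depth sensing (axial noise growth,
flying pixels), occlusion shadows, multi-view registration error, and
damage morphologies beyond clean dents and cracks (bruises without
geometric relief are invisible to any purely geometric method). Dent
severities were calibrated so the generated curvature contrast between
defects, stems and intact surface reproduces the regime observed on real
heads; absolute detection rates on real scans will depend on sensor noise
and damage populations not represented here.

## Known limitations

- κ-threshold extraction marks the high-curvature *edge and wall* of a
  defect, not its flat collapsed floor, so detected regions systematically
  under-cover the full damaged area (region-overlap scores against
  whole-depression ground truth plateau well below 1); area estimates
  inherit this edge bias.
- Shallow smooth dents (≲4 mm relief at these sampling densities) fall
  below the curvature threshold and are classified intact; lowering the
  threshold toward stem-level curvature trades these misses for false
  alarms on leaf stems.
- The shape-parameter stage depends on quadric fits that are meaningless
  on one-sided (rim) neighbourhoods; its threshold S* is an extreme
  statistic and unstable across scenes (the reason it defaults off).
- Single-viewpoint scans only; no multi-view fusion or registration.
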