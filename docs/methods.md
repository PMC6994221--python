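# Methods

This note records the models `ryrarray` implements, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions, so that results can be interpreted and reproduced.

## Tetramer geometry and the arrangement classifier

A tetramer is a square of side `s` (default 27 nm, giving the 729-nm²
footprint used throughout) with centre `(x, y)` and in-plane orientation
`θ`, reduced modulo 90° because of the square's 4-fold symmetry. Geometry is
strictly 2D: tetramers are taken as already mapped into the plane of their
dyad, and membrane curvature is out of scope. Within one array (one
tomogram's dyad) footprints may not overlap by more than a tolerance
(default 1 nm², the scale of manual box-placement error).

For a pair of equal-sided squares:

- `Δθ` is the angular difference folded into [0°, 45°]; the pair is
  *parallel* when `Δθ ≤ angle_tol` (default 10°). The tolerance is not
  published; 10° is tight enough to separate checkerboard rows from rotated
  neighbours and loose enough for manual-fit jitter, and it is configurable.
- For parallel pairs the centre displacement is rotated into the frame of
  the mean orientation (for `Δθ ≤ 10°` the mean-normal approximation
  deviates from either edge normal by < 1.5 % and is ignored). Each frame
  axis `u` yields a candidate facing-edge pair with gap `|d·u| − s`; the
  *separating axis* — the axis with the smallest non-negative gap, or the
  least-negative one if the squares interpenetrate within tolerance —
  defines the reported gap, and the overlap is the intersection of the two
  facing edges' projections on the perpendicular axis, clipped to `[0, s]`.

Classification of a parallel pair: adjacent iff `gap < 3 nm` and
`overlap > 0`; then *checkerboard* if `overlap < 18 nm` (= 2/3 · 27 nm) and
*side-by-side* if `overlap ≥ 18 nm`. Boundary conventions are strict on the
published "less than" thresholds (`gap < 3`, checkerboard `overlap < 18`;
an overlap of exactly 18 nm is side-by-side) and exclusive at zero overlap:
a corner-to-corner contact does not create adjacency, because the two
categories are defined by the amount of edge overlap. Per tetramer, the
labels of all qualifying neighbours aggregate to one of
checkerboard / side_by_side / both / isolated. Neighbour search uses a
KD-tree pruned at the exact adjacency reach `√((s+3)² + s²)`, which cannot
discard a qualifying pair, and is exhaustive for small arrays.

## Alpha shapes and coverage

Cluster and array boundaries are alpha shapes built from the Delaunay alpha
complex: the union of triangles whose circumradius is at most the disk
radius `α`. The area is the summed face area and never exceeds the
convex-hull area; the boundary polygons are exported for display. The
study's alpha value is not published; the default is `α = 50 nm`, matching
the cluster linkage scale so that point sets considered one cluster remain
one connected shape. The coverage fraction of an array is
`n · s² / area(alpha shape of all 4n corners)`; a single tetramer covers its
own footprint (coverage 1), and values slightly above 1 can occur when the
alpha boundary cuts footprint corners.

## dSTORM pipeline

1. **QC.** Keep blinks inside a 150-nm z slab around the surface with
   `σ_xy ≤ 10 nm`, `σ_z ≤ 40 nm` and goodness of fit `≥ 0.9`; then remove
   survivors whose nearest surviving neighbour (3D distance) is farther
   than 30 nm. The stage order is fixed — quality first, neighbour test
   second — so that neighbour support comes only from believable
   localizations, and the neighbour test runs once rather than to a fixed
   point. Both choices are configurable.
2. **Rasterization.** Blinks map onto half-open 10-nm pixels anchored at
   the minimum x, y of the filtered input. A pixel holding exactly one
   blink with no lit pixel in its 8-neighbourhood is treated as empty
   (applied simultaneously to the initial lit set).
3. **Clustering.** Single-linkage connected components of lit pixels with
   pixel-centre separation ≤ 50 nm; every lit pixel lands in exactly one
   cluster, and clusters are ordered by their minimum pixel index for
   deterministic output.
4. **Areas and filtering.** Cluster areas are alpha-shape areas over lit
   pixel centres (not pixel outer edges; the ≤ one-pixel-width bias is
   uniform across groups). Clusters with fewer than three non-collinear
   pixel centres are degenerate and dropped; clusters below 1600 nm² are
   dropped as coverslip noise — this same filter removes isolated single
   tetramers, which is its stated purpose, so no separate singleton rule
   exists. The strict `area < 1600` comparison carries a 10⁻⁶ slack so a
   boundary cluster (e.g. a 5×5-pixel block whose hull is exactly
   1600 nm²) is not lost to floating-point rounding.
5. **Tetramer counts.** `N = round(A · c / 729 nm²)`, rounding halves away
   from zero, with `c` the group-level coverage fraction from tomograms.
   Because a single scalar multiplies every area, the median count equals
   the rounded transform of the median area up to rounding ties.

## Distribution comparison

Nearest-neighbour distances, cluster areas and tetramer counts are compared
as empirical CDFs with the k-sample Anderson–Darling test in its rank/
midrank form — the data carry heavy ties (0.1-nm distance resolution,
integer counts). The statistic is standardized by its exact null mean and
variance, and the p-value interpolates the published standardized critical
values (a quadratic in the critical value fitted to log significance at the
seven tabulated levels from 0.25 to 0.001). Outside the tabulated range the
log-p curve continues linearly with the boundary slope, keeping p monotone
and strictly inside (0, 1) rather than clamping it; the tail extrapolations
are approximate and should be read as orders of magnitude. Pairwise group
comparisons are reported uncorrected alongside the k-sample omnibus, with
significance flagged at α = 0.01 by default. Formal bimodality or
mode-finding tests are out of scope; the 28/34-nm modes are descriptive
histogram features.

## Hierarchical spark statistics

Spark parameters are treated as log-normal: amplitude, FDHM, FWHM and spark
mass are compared on the log scale, while frequency normalized to SR
content is analysed untransformed (it is approximately normal). Sparks nest
in cells, cells in animals, and ignoring that nesting pseudo-replicates;
the group comparison therefore uses a hierarchical bootstrap of the
group-mean difference. The group mean is the mean of rat means of cell
means (equal animal weights). Each bootstrap replicate resamples rats with
replacement, then cells within each drawn rat, then sparks within each
drawn cell (B = 2000 by default), and the two-sided p-value is
`2 · (min(#{Δ* ≤ 0}, #{Δ* ≥ 0}) + 1) / (B + 1)`.

Calibration is a genuine trade-off here. The multistage bootstrap
over-estimates the sampling variance of a group mean (the variance of level
k enters k times), which alone would make the test conservative; with only
four animals per group the estimated variance is also heavy-tailed, which
alone would make a normal-theory test anticonservative. At realistic
designs (4 rats × 5 cells × 30 sparks, between-cell variation exceeding
between-animal variation) the two effects largely offset, and the measured
type-I error at α = 0.05 is 0.04–0.08 over 300-replicate simulations, with
power > 0.95 against a 1.5× multiplicative group effect. Note the p-value
floor `2/(B+1)`: with fifteen comparisons Holm's smallest critical value is
`α/15`, so B must be ≥ ~600 for any rejection to be possible at α = 0.05
(the default 2000 is safe). A mixed-effects model is a reasonable
alternative estimator; the bootstrap was chosen because its contract —
remove rat- and cell-level variance, produce one two-sided p per pair — is
exactly what the downstream ledger needs, with no distributional assumptions
at the animal level.

The Holm–Bonferroni ledger ranks the m pairwise p-values ascending, sets
the critical value at rank k to `α/(m−k+1)`, and rejects sequentially while
`p < critical` (strict inequality), stopping at the first failure. For six
groups, m = 15 and the smallest critical value is `α/15`.

## Synthetic generators

The generators emulate the *structure* of the study's three data streams;
they are the ground truth against which the pipeline is tested.

- **Arrays.** Motifs — side-by-side pairs at 28-nm centre spacing (1-nm
  edge gap), checkerboard pairs at 34 nm (axial separation 28 nm, lateral
  offset √(34²−28²) ≈ 19.3 nm, projected overlap ≈ 7.7 nm), mixed triples
  (one central tetramer with one neighbour of each kind) and isolated
  singletons — are placed on a shuffled coarse grid (250-nm spacing) with
  random rigid rotations, keeping distinct motifs far beyond the 40-nm
  adjacency reach. Per-tetramer Gaussian jitter (default σ = 0.6 nm
  positional — chosen so the centre-to-centre distance spread ≈ 0.85 nm
  matches the sub-nm side-by-side spread reported from tomograms — and 2°
  angular) is redrawn, up to a bounded number of retries, until the motif
  still satisfies the non-overlap invariant *and* every member still
  classifies to its intended label; the returned labels are thus ground
  truth by construction. Without the label re-check, nominal 1-nm gaps
  against the 3-nm threshold would silently flip a few percent of labels
  and the generator's truth would not be truth. Default fractions
  (0.50/0.28/0.08/0.14) mirror a control-condition arrangement.
- **Blink clouds.** Per footprint, a Poisson number of blinks (mean 50)
  lands uniformly on the footprint plus Gaussian localization noise of the
  blink's own σ_xy; quality columns are drawn inside the QC windows, a
  configurable `fail_fraction` is pushed beyond one threshold, and uniform
  coverslip background (default 2 blinks/µm²) is added. Not emulated:
  photoswitching kinetics, frame correlation, drift, emitter re-blinking
  statistics — so passing tests demonstrate the pipeline's geometry and
  filtering logic, not robustness to photophysics artefacts.
- **Sparks.** Log-normal parameters with additive rat- and cell-level
  random effects on the log scale (defaults: geometric means 0.45 ΔF/F₀,
  25 ms, 2.0 µm; spark-level log-sds 0.5/0.4/0.3; rat sd 0.10, cell sd
  0.15; 4 rats × 5 cells × 30 sparks per group) and per-cell frequency with
  an SR-content covariate. Six default treatment groups carry
  multiplicative effects in the direction the study reports (immunophilins
  suppress, phosphorylation enhances); magnitudes are illustrative, not
  fitted.

All generators are bit-reproducible for a fixed seed; independent seed
streams are spawned per component.

## Numerical conventions and degenerate inputs

- Units: nm for lengths, degrees for angles, ms / µm / ΔF/F₀ for sparks.
- Rounding of tetramer counts: half away from zero.
- Alpha-shape inputs need ≥ 3 non-collinear points; degenerate point sets
  raise a specific error (or drop the cluster inside the pipeline).
- Single-tetramer arrays have no nearest neighbour (error) but coverage 1.
- Empty localization lists flow through QC/rasterization as empty outputs.
- CSV readers parse floats in round-trip precision, so write∘read is
  bit-identical on canonical files; schema violations name the offending
  file line.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic data
at desk scale: 2000-tetramer arrays for fraction recovery, five planted
blink clouds of 2500 localizations for cluster recovery, 500 null
replicates for the Anderson–Darling type-I rate and 300 for the
hierarchical bootstrap. These sizes were chosen to bound Monte-Carlo error
comfortably below the tolerances being checked.

## Known limitations

- 2D only; tetramer mapping from tomograms (tilt, plane fitting) is
  upstream and out of scope, as is spark detection from line scans.
- The alpha parameter and the classifier's angular tolerance are declared
  defaults, not values recovered from the original analysis software.
- The AD p-value is asymptotic; for very small samples an exact permutation
  test (used as the oracle in the test suite) is preferable.
- The hierarchical bootstrap's calibration argument above is specific to
  designs with several animals and many observations per cell; with two
  animals per group its p-values should not be trusted.
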