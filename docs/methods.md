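# Methods

## The measurement model

`surfconn` quantifies white-matter connectivity *at each cortical vertex*
rather than per lobe or parcel. Given a triangulated cortical surface (mm
world space) and a tractogram registered to the same space, a streamline
is attributed to a vertex when one of its two extremities lies within the
**selection radius** (default 5 mm, Euclidean closed ball) of that
vertex. Streamlines shorter than 3 mm are removed beforehand. Tractography
streamlines carry no direction, so both extremities are eligible
independently; a streamline whose two extremities both fall inside one
vertex's ball contributes two entries there (no deduplication rule is
imposed — the symmetric choice). The **ending vertex** of a selected
extremity is the globally nearest mesh vertex to the streamline's *other*
extremity, with exact distance ties broken by lowest vertex index for
determinism.

At every vertex with at least one attributed streamline:

* **mean tracts' length** — mean of the attributed streamlines' lengths
  (arc length, i.e. summed segment norms). Unweighted by default;
  with 1/length weights it becomes the harmonic mean.
* **CI_short(T)** = 100 · Σ w·1{L ≤ T} / Σ w and
  **CI_long(T)** = 100 · Σ w·1{L > T} / Σ w, with per-streamline weight
  w = 1/L by default (see below) or w = 1 when unweighted.

The default cut-off is T = 30 mm (a group-average mean tract length), and
sensitivity sweeps run 5–30 mm (CI_short) and 30–60 mm (CI_long) in 5 mm
steps.

Two deliberate conventions:

1. **Half-open boundary.** Short is L ≤ T and long is L > T. Defining both
   inclusively at the boundary would double-count streamlines of length
   exactly T; the half-open convention makes CI_short(T) + CI_long(T) =
   100 an exact partition identity (verified to float precision, < 1e-9,
   in the acceptance suite). The boundary set has measure zero for
   continuous length distributions, so this choice is numerically
   immaterial.
2. **1/length weighting.** Deterministic tractography reconstructs a
   fiber bundle with a streamline count roughly proportional to its
   length. Weighting each streamline by the inverse of its length removes
   this bias from all *counts* (the CIs, termination proportions,
   sulcus/gyrus fractions), so CI counts are weighted by default. The
   mean tracts' length is, by definition, a mean of lengths — it defaults
   to the plain arithmetic mean, with the weighted (harmonic) variant
   available behind the same flag, since the literature does not pin this
   down.

Vertices with no attributed streamline are **invalid** (NaN sentinel),
excluded from smoothing stencils and statistics. Zero-filling them would
bias CI group comparisons toward zero wherever coverage is sparse.

Auxiliary maps: termination proportion maps (where the streamlines
starting at a seed vertex end, as weighted fractions summing to 1),
sulcus/gyrus termination fractions (labels from the sign of mean
curvature, positive in sulci per the FreeSurfer convention; the boundary
curvature 0 is labelled gyrus), and termination angles (angle between the
terminal polyline segment at the ending side and the surface normal at
the ending vertex, folded to [0°, 90°] because fibers are undirected).

## Surface smoothing

Maps are smoothed by iterated nearest-neighbor averaging: each valid
vertex is replaced by the unweighted mean of itself and its valid 1-ring
neighbors. The stencil includes the center vertex (stable, standard) and
invalid vertices are simply dropped from their neighbors' stencils.

The iteration count realising a target kernel width depends on the mesh's
edge lengths, so it is **calibrated empirically** rather than taken from
a closed formula: unit impulses are placed at a few vertices sampled
evenly over the index range, smoothed step by step, and each impulse
response is fitted to a Gaussian in geodesic distance (least squares of
log-response against squared distance, zero intercept, restricted to
responses above 1e-4 of the peak). Geodesic distance is approximated by
graph shortest paths over edge lengths — adequate at the 10 mm default
FWHM relative to ~1 mm edges, and far cheaper than exact polyhedral
geodesics. The calibrated count is the smallest n whose mean fitted FWHM
reaches the target, so FWHM(n−1) < target ≤ FWHM(n) by construction; the
whole calibration report is retained for inspection. On a 40 962-vertex
icosphere with ~1.05 mm edges the 10 mm target calibrates to 24
iterations (measured 9.78 mm at 23, 10.02 mm at 24).

## Group statistics

Per-vertex OLS of the subject maps on a design with intercept, binary
group (0 = controls, 1 = patients), age, sex, and optionally white-matter
volume. The group contrast's t uses df = n − rank(X); a vertex enters
only if valid in every subject. Perfect fits (zero residual up to
rounding) are resolved explicitly: t = 0 for a null contrast, ±inf under
exact separation — never a ratio of float noise.

Cluster-wise familywise-error correction uses the **max-cluster-area
permutation null**: supra-threshold vertices (default two-sided p < 0.001
on the t map; the forming threshold is a free parameter and results at
coarse thresholds should be read accordingly) are grouped into connected
components over mesh adjacency, each cluster's area is the sum of its
per-vertex areas (one third of incident triangle areas, mm²), and the
null is built by Freedman–Lane residual permutation: residuals of the
reduced (covariates-only) model are row-permuted, added back to the
reduced fit, and the full model is re-estimated; each permutation
contributes its largest cluster area over both signs. Corrected p-values
use the unbiased (1 + #{null ≥ observed}) / (1 + n_permutations)
estimator, so the attainable minimum is 1/(n_permutations + 1); the
default 1000 permutations resolves the conventional cluster-wise
significance level of 0.01. Positive and negative clusters are detected
separately and never merged.

Cluster **effect size** is Cohen's d of the per-subject cluster-mean
values, (mean controls − mean patients)/pooled SD, so positive d means
controls exceed patients. This is one reasonable interpretation of a
cluster-level effect size; it is not covariate-adjusted.

**Reliability** across repeated acquisitions is ICC(2,1) — the two-way
random-effects, absolute-agreement, single-measure intraclass
correlation, computed per vertex from the classical ANOVA mean squares —
plus the coefficient of variation, 100 · within-subject SD /
|within-subject mean|, averaged over subjects. ICC(2,1) was chosen
because scan–rescan sessions are random "raters" whose absolute agreement
is the quantity of interest. The implementation is cross-checked against
pingouin's ICC(A,1) in the test suite.

## The synthetic generator

The generator reproduces the statistical structure the method consumes,
not anatomy:

* **Mesh** — a closed icosphere (default subdivision 3, radius 50 mm, a
  hemisphere-like scale), or a sinusoidally folded sheet whose analytic
  second derivative provides a ground-truth sulcus/gyrus sign field.
* **Streamlines** — each samples a start vertex uniformly, a class
  (short with probability p_short = 0.6 by default), and a target length
  from the class distribution (short 15 ± 5 mm, long 45 ± 10 mm, chosen
  so the overall mean length sits near the 30 mm cut-off; draws below
  3.5 mm or beyond the mesh's geodesic diameter are resampled). The end
  vertex is the one whose graph-geodesic distance best matches the
  target; the polyline follows the shortest path with small interior
  jitter (0.2 mm) and extremity displacement sampled uniformly in a ball
  (default radius 1 mm) to emulate endpoints lying *near*, not on, the
  surface. Realized lengths are therefore quantized by the mesh edge
  length; ground truth records class, target and realized length, and
  the true start/end vertices.
* **Group effect** — inside a geodesic patch, patients' p_short is
  shifted by delta_p_short, emulating a spatially confined change in the
  short/long mixture.
* **Cohorts** — either the full per-subject tractogram→metrics pipeline,
  or a direct map simulation with explicit variance components
  (baseline CI 60%, between-subject SD 4, per-vertex SD 6, on the CI
  percent scale; the patch shifts patients by 100·delta_p_short points).
  The direct mode is used for the repeated-cohort calibration studies
  because it makes the exchangeability-under-the-null and the planted
  effect exactly known.

What the generator does **not** emulate — curved fiber geometry, partial
voluming, registration error, spatially correlated noise, hemispheric
asymmetry — bounds what passing tests show: they validate the estimator
and its inference under known truth, not robustness to real acquisition
artifacts.

All randomness descends from one integer seed through numbered
`SeedSequence` substreams, so components can be regenerated independently
and outputs are bit-identical across runs.

## Problem sizes and numerical choices

The validation studies run at deliberately compact sizes that keep every
quantity's Monte Carlo error well inside its decision band: the type-I
study uses 200 null cohorts of 15 subjects/group on a 162-vertex mesh
with 500 permutations (95% binomial band 0.020–0.080 around the nominal
0.05); planted-effect recovery uses 20 cohorts of 20 subjects/group on a
642-vertex mesh; smoothing calibration uses the 40 962-vertex, ~1 mm-edge
icosphere; oracle-equivalence checks run five configurations up to 2 562
vertices × 3 000 streamlines against a dense all-pairs search.

Other numerical details: the radius test is a closed ball (≤); nearest-
vertex ties break to the lowest index; CI values at a vertex are exact
ratios of weight sums, so the partition identity holds to ~1e-14;
smoothing is a convex combination, hence range-containing and exact on
constants; permutation p-values are deterministic given the seed.

## Known limitations

* Euclidean (not geodesic) selection radius: extremities near a sulcal
  bank can be attributed to vertices on the opposing bank. This mirrors
  the method being implemented; a geodesic variant would need a
  surface-constrained distance.
* Vertex correspondence across subjects is assumed given (as after
  spherical registration); no resampling machinery is provided.
* The permutation test assumes exchangeable subjects under the null;
  heteroscedastic groups are not specifically handled.
* The cluster-forming threshold is a free parameter with the usual
  cluster-inference caveats.
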