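# Methods

This note documents the statistical procedures implemented in `betaspace`,
the choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Beta-diversity partition

For each unordered pair of sites the species counts `a` (shared), `b` and
`c` (unique to either site) define

```
beta_total = (b + c) / (a + b + c)          # Jaccard dissimilarity
beta_repl  = 2 min(b, c) / (a + b + c)      # balanced species replacement
beta_rich  = |b - c| / (a + b + c)          # richness surplus
```

with `beta_total = beta_repl + beta_rich` an exact identity. The framework
is incidence-based: abundance tables must be binarised (presence = at least
one individual) before partitioning. A pair of empty sites has no defined
dissimilarity; the strict mode raises, the tolerant mode emits NaN and
excludes the pair from summaries — silent 0/0 handling would corrupt the
Mantel and ordination inputs downstream. Matrices are stored dense; the
intended problem size is tens of sites.

## Coordinates and distances

Decimal-degree coordinates are projected to planar km by an equirectangular
projection at the mean latitude (111.32 km per degree). For island-scale
extents (≤ 50 km) the distance error against the great-circle (haversine)
distance is below 1%, which the test suite verifies. Distance-decay slopes
are therefore in units of dissimilarity per km. The geographic distance
matrix is plain Euclidean on the projected coordinates.

## Landscape disturbance index

Land-cover classes are scored 0 (natural forest) through 5
(urban/industrial). The index of a focal cell is a distance-weighted mean
over a square window, `D = 100/5 * Σ w L / Σ w`, with `w = 1/d`
(centre-to-centre distance in cell units) for neighbours and `w = 2` for the
focal cell — double the weight of an adjacent cell; `D` spans 0–100 by
construction. Choices made here:

* The neighbourhood is truncated at a configurable Chebyshev radius
  (default 10 cells = 1 km at 100 m resolution). `1/d` contributions beyond
  that range add less than ~2% at this cell size; an unbounded whole-map sum
  would be quadratic in map size for no practical gain.
* Edge cells normalise by the realised in-grid weight sum; no phantom cells.
* No-data cells are excluded from numerator and denominator; a fully masked
  window yields a masked output cell.
* Site extraction uses the half-open, lower-left-inclusive cell convention.

Before entering the predictor matrix the per-site index is transformed with
`ln(d + 1)` (the offset keeps zero-disturbance sites legal) to reduce skew.

## Environmental predictor matrix

Fixed pipeline order: log-transform disturbance → standardise every column
to mean 0, SD 1 (sample SD, n−1) → PCA of the five climate variables →
assemble the final ten columns (Litter, NumSpp, Soil_pH, OrgMat, DUrb,
Altitude, Slope, Climate_PC1, Climate_PC2, Disturb). Missing values are
rejected, never imputed.

The climate PCA runs on the correlation matrix (via SVD of the standardised
data): the variables mix units (mm, %, °C), so covariance PCA would be
dominated by precipitation. Component signs are arbitrary up to the
eigensolver; each component is flipped so its largest-magnitude loading is
positive, making runs reproducible across platforms.

## Moran's eigenvector maps

Four neighbour graphs of increasing connectivity are supported — minimum
spanning tree, relative neighbourhood graph, Gabriel graph, Delaunay
triangulation — whose edge sets nest (`mst ⊆ rng ⊆ gabriel ⊆ delaunay`).
RNG and Gabriel are computed by their defining pair/witness criteria
(O(n³), trivial at these n); MST and Delaunay come from `scipy`. Edge
weights are binary, `f1 = 1/d`, or `f2 = 1 − d/d_max`, with `d_max` the
longest edge *of that graph* (per-graph, not global). Twelve candidate
spatial models result.

Each weight matrix `W` is double-centred (`Ω = H W H`, `H = I − 11'/n`) and
eigendecomposed. Eigenvectors with eigenvalue above `1e-10` are retained:
they are centred, orthonormal (unit norm was chosen over √eigenvalue
scaling; scaling is irrelevant for selection and regression R²) and their
Moran's I values are ranked identically to their eigenvalues, so leading
vectors describe broad-scale positive autocorrelation. Negative-eigenvalue
vectors (negative autocorrelation) are out of scope.

### Spatial model selection

The response for selection is the set of positive principal-coordinate axes
of the dissimilarity matrix, scaled by the square roots of their
eigenvalues, so that residual sums of squares pooled across axes weight
each axis by the inertia it carries. For each of the 12 candidates the
eigenvectors are ranked by individual R², entered one at a time, and each
nested model is scored with

```
AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n − p − 1),   p = #eigenvectors + 1
```

pooling RSS across response axes; with a univariate response this is
exactly the standard least-squares AICc. The path starts at the
intercept-only model (so an unstructured response can select zero
eigenvectors) and is truncated where `n − p − 1 ≤ 0`. The candidate's best
model is the path minimum, with ties within 0.01 resolved toward fewer
eigenvectors; the overall winner is the candidate with the lowest best
AICc (ties toward fewer vectors, then a fixed graph/scheme order).

Because eigenvectors are ranked by fit before AICc scoring, the procedure
is mildly liberal for a *univariate* response: with a planted signal plus
noise, one spurious eigenvector can survive alongside the true set. The
test suite therefore checks that a noise-free planted response is recovered
exactly and that a noisy one (SNR 10) yields a retained set *containing*
the planted subset; for the multivariate pooled response actually used on
beta matrices, the pooling dilutes the selection bias and structureless
communities retain at most a couple of eigenvectors.

## Constrained ordination (CAP / db-RDA)

The dissimilarity matrix is Gower-centred and eigendecomposed; axes for
positive eigenvalues (relative threshold `1e-9`) are kept and negative
inertia is reported but its axes dropped — no Lingoes/Cailliez correction,
matching the common default of distance-based RDA implementations and
keeping R² inside [0, 1]. R² is the fraction of positive-axis inertia
explained by the column-centred predictors,
`pseudo-F = (R²/m)/((1−R²)/(n−m−1))`, and the permutation test permutes
site labels unrestrictedly (raw-data permutation; residual-based schemes
are not implemented), with `p = (#{F* ≥ F} + 1)/(n_perm + 1)`. Adjusted R²
uses Ezekiel's formula `1 − (1−R²)(n−1)/(n−m−1)` and may be negative.

Forward selection implements the double stopping rule: a global test with
all candidates must pass at `alpha` first; candidates are then ranked by
gain in R² (ties broken alphabetically), gated by a marginal permutation
test (the candidate's raw values are permuted, selected columns held
fixed), and the procedure stops when the best candidate's marginal
`p ≥ alpha` or when accepting it would push the cumulative adjusted R²
above the global model's (reported as `adjR2_ceiling`; the candidate is not
accepted).

## Variation partitioning

Two-set partitioning from three constrained ordinations (environment,
space, both): `pure_env = adjR2_both − adjR2_spatial`,
`pure_spatial = adjR2_both − adjR2_env`,
`shared = adjR2_env + adjR2_spatial − adjR2_both`,
`unexplained = 1 − adjR2_both`. The fractions are exact arithmetic
identities of the three adjusted R² values; small negative fractions are
sampling artefacts of the adjustment and are reported unclipped with a
warning. Only the three full models are permutation-tested; individual
fractions are not.

## Mantel tests and distance decay

The Mantel statistic is the Pearson correlation over the n(n−1)/2
unordered-pair entries; significance comes from simultaneous row/column
permutations of one matrix. The default tail is directional in the sign of
the observed r (matching one-sided reporting of negative decay
relationships); note that choosing the tail from the observed sign is
anticonservative under the null by construction, so calibration checks and
conservative analyses should use `tail="two-sided"`. For `n ≤ 7` an
exhaustive mode enumerates all n! relabellings and returns the exact
permutation p. The decay intercept/slope are descriptive OLS on the
dependent pairs; standard errors are deliberately not reported.

## Synthetic communities

`simulate_sites` draws uniform coordinates in a square extent (default
30 km, matching a ~30 km maximum inter-site span) and builds each
environmental column as a mixture of a west–east gradient, a Gaussian
random field (kernel-grid construction, default range 8 km) and white
noise, rescaled to a realistic island-survey mean/SD roster; the five
climate columns share one smooth latent factor (temperature opposing
humidity/precipitation) so that a two-component climate PCA is the natural
reduction.

`simulate_community` gives each of the 31 species a Gaussian niche on the
standardised altitude gradient (optimum uniform over the realised range,
width 1 z-unit) and its own latent spatial field; occurrence probability is
`logistic(base + env_effect·niche + spatial_effect·field)`, with `base`
calibrated by bisection so the expected per-site richness matches
`occupancy_base` (default 5 of 31 species). Scenarios E/S/ES/N switch the
two channels on and off. Defaults are 26 sites and 31 species.

The effect strengths (`env_effect = 8`, `spatial_effect = 3` logit units)
were fixed by requiring that single-channel scenarios produce explained
adjusted-R² fractions of the magnitude field surveys of this kind actually
report (roughly 0.15–0.3 for a selected predictor set); with Bernoulli
incidence noise at ~5 occupied species per site, weaker effects leave
essentially no detectable signal. What the generator does *not* emulate:
species interactions, abundance structure, detection error of trapping,
temporal turnover, and shared spatial fields between species (each species'
field is independent). Passing the scenario-contrast tests therefore shows
that the pipeline attributes variation to the channel that generated it
under idealised sampling — not that field data of this size always carry
recoverable signal.

## Numerical conventions

* Positive-eigenvalue thresholds: `1e-10` absolute for MEM bases, `1e-9`
  relative for PCoA.
* Deterministic sign conventions (largest-magnitude element positive) for
  PCA loadings and MEM eigenvectors.
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives fixed per-stage offsets from one global seed so stages
  reproduce standalone.
* Square matrices are written to CSV with `%.17g`, and read back with
  round-trip float parsing, so write→read is bit-exact.

## Problem sizes used in the test suite

The suite exercises the statistically expensive checks at desk scale chosen
to keep the whole run under a minute while leaving the Monte-Carlo error
well inside the asserted bands: 1000 random matrices for the additivity
identity, 200 point sets for the graph hierarchy, 200 replicates at 199
permutations for the type-I calibration bands, 60 replicates for planted
eigenvector recovery, and 50 paired seeds for the scenario contrast.
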