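# Methods

This document records the statistical methods implemented in
`nichedyn`, the default parameters and why they were chosen, and the
known limitations. Module references are to `src/nichedyn/`.

## 1. Synthetic worlds (`synthetic.py`)

Each region's climate is a stack of five bioclim-style variables on a
regular lon/lat grid (default 80×80 cells at 0.1°). A layer is the sum
of a deterministic linear trend in longitude/latitude (fixed slope and
orientation per variable) and a Gaussian random field, generated as
white noise smoothed with a Gaussian kernel and rescaled to a
per-variable sill standard deviation. Regions drawn for the same scenario share the
trend but have independent noise realizations, so "the same niche in
two regions" still faces different realized climates.

A species' niche is a Gaussian suitability function in climate space
with mean vector and covariance matrix fixed by the scenario.
Occurrences are sampled *by cell*: the per-cell suitability is the
Gaussian density evaluated at the cell's climate, normalized over land
cells (`true_cell_suitability`), a multinomial draw picks cells, and
each point is jittered uniformly within its cell. This makes
`true_cell_suitability` an exact oracle for the sampling distribution —
the validation tests compare estimators against it directly.

Presets (two ranges of n = 300 unless noted):

| preset | construction |
|---|---|
| `identical` | same niche mean and covariance in both regions |
| `nested` | same mean, range B covariance 4× (B's niche strictly contains A's) |
| `shifted` | B's mean displaced a few niche SDs; B's climate trend shifted with it |
| `disjoint` | means 7.5 pooled niche SDs apart in every variable |
| `five_range_lilium_like` | one native range plus four introduced ranges with n = 105/315/200/30/70 |

Realism limits: climates are stationary Gaussian fields with linear
trends, not real topography; occurrence sampling has no spatial bias,
detection error, or dispersal limitation; niches are single Gaussians.
The generator is a validation instrument, not a simulator of real
biogeography.

## 2. Environmental space (`espace.py`)

**Background.** Each range's background is the set of land cells within
a bounding buffer (default 0.3°) of its occurrences, built with
shapely; if the occurrences are collinear the buffered bounding box is
used.

**PCA-env.** The PCA is calibrated on the *pooled background climates*
of all ranges (each variable standardized by the pooled mean/SD), so
every range's occurrences and backgrounds are projected into one shared
space. Axis signs are fixed deterministically (largest-magnitude
loading positive) so results do not flip between runs. The first two
axes carry the analysis; the explained-variance fractions of all axes
are reported.

**Gridding and kernel density.** Scores are histogrammed on an R×R grid
(default R = 500) spanning the pooled background scores, then convolved
with a Gaussian kernel (`scipy.ndimage.gaussian_filter`). The bandwidth
per axis is Silverman-style, σ·n^(−1/6). Two numerical choices matter:

- `KDE_TRUNCATE = 8.0`: the kernel is truncated at 8 bandwidths rather
  than scipy's default 4. The 100% occurrence outline is defined as
  cells with smoothed density above a relative floor of 1e-8, which the
  Gaussian kernel reaches ≈ 6σ from a point mass. With truncation at
  4σ the outline would be set by the arbitrary hard cutoff instead of
  the floor, and the dynamics indices became sensitive to it. At 8σ
  the floor governs, matching the behaviour of an untruncated kernel.
- Availability-corrected occupancy: `z_cor ∝ z_occ / z_avail` on cells
  with non-negligible availability, renormalized. This is the default
  occupancy for reporting D and the dynamics indices, because it
  removes the imprint of what climates each region offers. The raw
  occurrence density `z_occ_raw` is kept alongside it.

**Outlines.** `occupied_mask_100` is the 100% outline above;
`quantile_outline(q)` gives the cells holding the top q fraction of
occurrence density.

## 3. Overlap, permutation tests, dynamics (`overlap.py`)

**Schoener's D.** `D = 1 − ½ Σ|p₁ − p₂|` over the grid, with both
occupancy grids normalized to sum 1. D ∈ [0, 1].

**Equivalency test.** The pooled occurrence scores of both ranges are
randomly re-split into the original sample sizes, densities are rebuilt
and D recomputed, `n_reps` times (default 100). Two conventions are
deliberate:

- *Bandwidth re-estimation.* Each permuted sample's density uses a
  bandwidth estimated from that sample, not copied from the observed
  one. The observed D was computed with own-sample bandwidths, so the
  permutation distribution is only exchangeable with it if the null
  replicates are treated identically; reusing the observed bandwidth
  made the null anti-conservative in calibration runs.
- *Raw-density policy for the null.* The permutation tests default to
  the uncorrected occurrence densities (`policy="raw"`), while D itself
  is reported on corrected occupancies. Reason: the availability
  correction clips each density to its own range's background, so when
  the two backgrounds do not overlap in E-space, the observed D *and
  every permuted D* degenerate to exactly 0 and the "lower" test has
  zero power precisely in the clearest niche-shift case. The raw
  densities keep the null informative; the two policies are decoupled
  (`compare_pair(policy=..., test_policy=...)`,
  `RunConfig.permutation_policy`).

**Similarity test.** Range 2's occurrence density is translated (by
integer grid shifts, no wrap-around) so its centroid lands on a random
available cell of range 2's background, clipped to that background,
renormalized, and compared to range 1's observed density.

P-values use the (r+1)/(n+1) convention, so they are never 0; the floor
at 100 repetitions is 1/101 ≈ 0.0099.

**Dynamics.** On the analog climate mask, with occupancy judged at the
100% outline: stability = share of range 1's occupancy on cells
occupied by range 2; expansion = 1 − stability (exact by construction);
unfilling = share of range 2's occupancy on cells *not* occupied by
range 1. The duality expansion(1→2) = unfilling(2→1) holds whenever
both directions use the same mask and occupancy policy. Indices above
0.1 are flagged ecologically relevant.

*Analog mask.* Default `"intersection"`: only cells available in both
ranges count, which is the honest comparison when both regions offer
overlapping climates. For backgrounds that are disjoint in E-space the
intersection is empty and the indices are undefined; pass
`analog_policy="full-grid"` to compute them on the whole grid instead
(they then trivially report expansion = unfilling = 1).

*Finite-sample spread.* At the preset n = 300, the corrected occupancy
of two samples from the *same* niche in *different* regions can differ
visibly where one region's background thins out: occasional
expansion/unfilling values up to ≈ 0.15 for truly identical niches are
sampling noise, not signal. The acceptance tests therefore check the
identical-preset dynamics at a pre-chosen seed with a ±0.02 tolerance
and the unit tests use a loose 0.2 bound.

## 4. Divergence vs availability (`divergence.py`)

A PCA with varimax rotation (statsmodels `rotate_factors`) is fitted on
the pooled occurrence + background climates, retaining axes with
eigenvalue ≥ 1 (Kaiser). On each axis, d_n = |mean(occ A) − mean(occ B)|
and d_b = |mean(bkg A) − mean(bkg B)|, each with a bootstrap percentile
CI (default 1000 resamples, α = 0.05); d_n's significance comes from a
Welch t-test. Verdict: **divergence** when d_b's CI lies entirely below
d_n's and d_n is significant; **conservatism** when d_n's CI lies
entirely below d_b's; otherwise **inconclusive**. The statistic is
exactly symmetric under swapping the two ranges. Backgrounds for this
test are drawn from the buffer influence zone around the occurrences
(default 20 km at 111.32 km/degree, latitude-uncorrected — adequate at
the mid-latitude desk scale of the synthetic worlds).

## 5. Geometric envelopes (`geometry.py`)

In 3-component standard-PCA space each range's occurrence cloud is
summarized by its minimum-volume enclosing ellipsoid (Khachiyan's
algorithm, tolerance 1e-6) and its convex hull (scipy/Qhull).
Intersection volumes use Monte Carlo: sample uniformly in one body's
bounding box, count points inside both; the binomial standard error is
reported alongside. Jaccard = V∩ / (V_a + V_b − V∩); Monte-Carlo noise
can push V∩ marginally above min(V_a, V_b), so values within 1% are
clamped into [0, 1] and larger violations raise.

## 6. Distribution models (`sdm.py`)

A MaxEnt-style presence–background model: L2-penalized logistic
regression (scikit-learn, `C = 1/reg_weight`) on standardized linear,
quadratic, and pairwise-product features. An ensemble of replicates
(default 20) each holds out 25% of presences for a test AUC against the
background. Projection clamps out-of-range climates to the calibration
envelope (`predict(x, clamp=True) ≡ predict(clip(x), clamp=False)`).
The binary threshold maximizes sensitivity + specificity on the
calibration data (lowest score among ties). `reciprocal_matrix`
calibrates one model per range and projects it into all ranges,
reporting mean/SD test AUC, the threshold, and the percentage of the
projection range's occurrences on suitable cells.

This is a stand-in for MaxEnt, not a reimplementation: it shares the
exponential-family form and clamping behaviour but uses plain L2
logistic loss rather than MaxEnt's feature-expectation constraints.

## 7. Pipeline (`pipeline.py`)

`run_all(RunConfig(...))` chains simulate → prepare → E-space → all
ordered pairwise comparisons → divergence → geometry → SDM → UPGMA
clustering of range niche centroids (average linkage on squared
Euclidean distances, ultrametric Newick output), writing each product
as CSV plus `manifest.json`. Failures are annotated with the stage
name. `config_hash` is a SHA-256 digest of the configuration
*excluding* `out_dir` (the output location does not change the
analysis), so the same analysis written to two directories shares one
hash and reruns are byte-identical.

## 8. Validation conventions

- Estimator-vs-truth checks use the expected-pipeline-density oracle:
  the known per-cell suitability is histogrammed on the E-space grid,
  convolved with the estimator's own kernel at the bandwidth implied by
  the true score moments, and availability-corrected — i.e. the exact
  expectation of the estimator, not the raw niche. Comparing the
  estimator to the raw truth instead would conflate estimator bias with
  smoothing, which is part of the definition of the statistic.
- Monte-Carlo validation samples use n = 10⁴ occurrences, large enough
  that the multinomial sampling floor on total-variation distance
  (≈ Σ√(2p(1−p)/(πn))/2) is well below the tolerances being tested.
- Permutation-test calibration is measured on re-splits of a single
  sample from one region (the textbook null). Two independent samples
  of the same niche in *different* regions are not an exact null for
  the equivalency test: realized cross-region differences are real, and
  the test is legitimately sensitive to them.

## 9. Limitations

- The E-space analysis uses only the first two PCA axes; structure in
  higher components is invisible to D and the dynamics indices (the
  3-D geometric module partially compensates).
- Kernel density on a fixed grid is resolution- and bandwidth-dependent
  near the support boundary; the defaults (R = 500, Silverman
  bandwidth, truncation 8σ, occupancy floor 1e-8) were chosen so that
  the identities E + S = 1 and the expansion/unfilling duality hold to
  numerical precision and the outline is floor-governed, but absolute
  index values still carry finite-sample spread at realistic n.
- The divergence verdict is per-axis; no multiple-testing correction is
  applied across axes.
- Great-circle distances in thinning use a spherical Earth; the buffer
  background uses a planar degree metric. Both are adequate at the
  sub-degree scales used here and are not suitable for continental
  polar geometries.
- The SDM is a regularized logistic surrogate; absolute suitability
  values are not comparable to MaxEnt's, though thresholded maps and
  AUC-based comparisons behave analogously.
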