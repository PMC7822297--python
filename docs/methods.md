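# Methods

This note records the statistical model behind `moultmap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that are not visible from the API.

## Record model and corrections

A record is one bird: identifiers (id, species, year, sex), feather isotope
values (δ¹³C on VPDB, δ¹⁵N on Air, δ¹⁸O on VSMOW, all ‰) and morphometrics
(feather growth rate mm/day, body mass g, tarsus mm, wing mm). Records are
held as rows of a pandas DataFrame with a fixed column schema; missing
cells are genuine missing values, never zeros.

Filtering drops records missing either assignment isotope, and — for a
configurable species list only — records with δ¹³C strictly below −23 ‰
(apparent outliers that cannot be separated from measurement error).
Filtering is idempotent and every drop carries a reason.

Corrections are exact affine shifts, so they commute with filtering and
leave all variance-based statistics unchanged:

* carbon: δ¹³C_corr = δ¹³C − L·Δ with Δ = 0.8 ‰ per trophic level and
  L = 2 (storm-petrels feed ≥ 2 levels above the phytoplankton that sets
  the isoscape), i.e. −1.6 ‰ total;
* oxygen: δ¹⁸O_corr = δ¹⁸O − D(hemisphere), defaults D = 10.4 ‰ (north)
  and 13.0 ‰ (south). `estimate_o18_discrimination` recovers D as
  mean(known-origin feathers) − mean(local water samples); with so few
  known-origin feathers available in practice (≈ 8) this is a point
  estimate with no useful standard error, which is why D is a constant,
  not a fitted parameter.

Raw and corrected columns are both kept; downstream functions state which
they consume (the tree runs on raw values by default — the corrections are
constant shifts and do not change any test statistic; assignment requires
the corrected columns).

## Conditional inference tree

The grouping stage is binary recursive partitioning in a conditional
inference framework with the bivariate response Y = (δ¹³C, δ¹⁸O).

At a node with n observations, for covariate X with transformation g
(identity for numeric, one-hot for categorical) and influence h(Y) = Y,
the linear statistic is T = Σᵢ g(Xᵢ) h(Yᵢ)ᵀ. Under the permutation null
its moments are the Strasser–Weber expressions; with g column-centered the
expectation vanishes and Cov vec(T) = (n/(n−1)) (GᶜᵀGᶜ) ⊗ V, where V is
the biased covariance of h. The test statistic is the quadratic form
c = dᵀ Σ⁺ d (pseudoinverse, rank from SVD at relative tolerance 1e-10),
referred to χ² with df = rank(Σ). A numeric covariate against the
bivariate response gives df = 2; a constant covariate or constant response
gives statistic 0 and p = 1 rather than an error.

P-values are Bonferroni-adjusted across the covariates tested at the node
(case-wise exclusion of missing covariate values, per test). The node
stops when min adjusted p > α (default 0.05 — the conventional a-priori
level) or when it holds fewer than 2 × min_node_size observations
(default 7). Otherwise it splits on the min-p covariate at the cutpoint
maximizing the standardized two-sample statistic dᵀV⁺d / a with
a = n_L(n−n_L)/(n−1): all observed-value boundaries are candidates subject
to min_node_size on both sides, ties go to the smaller cutpoint, and the
reported numeric cutpoint is the largest observed value on the left side
(producing "≤ 23.5 mm"-style rules). Categorical splits enumerate the
2^(k−1)−1 binary partitions. Rows missing the chosen split covariate are
sent to the child with more complete-case observations (there are no
surrogate splits). Nodes are numbered depth-first, left first, root = 1.

Only asymptotic χ² p-values are provided (no Monte-Carlo resampling).
Known property: with many covariates the Bonferroni adjustment plus the
positive dependence of tests sharing one response makes the tree
conservative — at α = 0.05 and eight independent null covariates the
measured any-split rate is ≈ 0.034 rather than 0.05. The calibration test
in the suite therefore uses a compact battery (one numeric + one
categorical covariate), where the measured rate is ≈ 0.045 and a binomial
band around α is informative about calibration rather than about
Bonferroni's conservatism.

Follow-up tests for describing terminal nodes: Welch t (scipy, with the
Welch–Satterthwaite df; an error is raised when both groups have zero
range), one-way ANOVA with Tukey HSD (scipy; pairs oriented
later-minus-earlier), and a one-way MANOVA Pillai trace. The Pillai
computation is in-package: H and E scatter matrices, V = tr(H (H+E)⁺), and
the standard F approximation with s = min(q_eff, k−1), where q_eff is the
rank of H+E — degenerate response dimensions are dropped, so a constant
second response reduces exactly to the univariate ANOVA F (statsmodels'
MANOVA is used as a cross-check oracle on non-degenerate cases in the test
suite). MANOVA df are Pillai's own (s(2m+s+1), s(2n'+s+1)), not the
univariate (k−1, N−k) pair sometimes printed alongside them.

## Assignment model

For corrected value y and an isoscape with cell means μ_c, per-cell SD
layer σ_iso and an extra uncertainty σ_extra, the unnormalized weight at
ocean cell c is the normal density N(y; μ_c, √(σ_iso²+σ_extra²)),
normalized to sum to 1 over ocean cells. When the isoscape carries no SD
layer, σ_extra defaults to the analytical uncertainties — 0.10 ‰ (δ¹³C)
and 0.50 ‰ (δ¹⁸O) — the only uncertainties that are always available.
If every σ_c is zero the surface degenerates to a uniform point mass on
exactly matching cells, and an error is raised when no cell matches.
The surface is exactly invariant to adding a common constant to the
isoscape and the feather value.

Group surfaces are the cell-wise arithmetic mean of the members'
normalized surfaces (each bird contributes equally; the mean preserves
normalization). Scaling is z-scoring over ocean cells with the sample SD
(n−1); `per_layer` (default — each map scaled by its own SD) or
`pooled_sd` (layers centered individually but divided by one SD pooled
across the stack, for reading groups of maps on a common scale). A
constant layer scales to all zeros with a warning. Combined maps are the
cell-wise sum of the two scaled layers; they are relative scores,
interpretable only against quantiles of their own map.

Quantile thresholds use the linear-interpolation empirical quantile over
ocean cells, and threshold masks are strict (value > threshold), so a
constant map has an empty top-quantile region. Jaccard similarity between
two maps is |A∩B|/|A∪B| of their binarized cell sets; the binarization
quantile is a free parameter (default 0.75, exposed as
`--jaccard-quantile`) because no canonical threshold exists — published
Jaccard values from other binarizations are therefore not comparable
targets.

## Validation battery

* **Chlorophyll contrast**: ocean cells are split at the surface's
  q-quantile (default 0.75) and the chlorophyll values of the two cell
  sets compared by Welch t, oriented high-area minus low-area.
* **Latitude prediction**: the Southern-Ocean relation
  δ¹³C = −8.52 − 0.26 × latitude is inverted with latitude read as
  degrees-South magnitude and re-signed (the only self-consistent
  reading); predictions north of −44° are flagged as north of the
  Subtropical Front and band statistics are suppressed. Band statistics
  (max, mean ± SD of scores at cell-center latitudes within mean ± SD of
  the predicted latitude) are compared to the map's 95 % quantile.
* **Observations**: sightings are averaged within 10°×10° bins anchored
  at (−90, −180); around each bin centroid, scores are averaged over
  ocean cells whose centers lie within a 1.1×10⁶ m great-circle buffer
  (haversine on a sphere of R = 6371 km, ≈ 9.9° of arc). Empty buffers
  are reported as missing, never dropped silently.
* **Eco-realms**: per-region mean ± SD of ocean-cell scores, membership
  by cell center (boundary centers go to the first-listed region), class
  `above_q95` / `mid` / `below_q50` against the map's own quantiles;
  land-only regions are `unavailable`.

## Synthetic-data generator

The generator is the testbed that defines the study conditions:

* δ¹³C isoscape: δ¹³C = −8.52 − 0.26·|lat| (+ optional zonal tilt), the
  same relation the latitude prediction inverts — so inversion is exact
  by construction south of the front, which is the point of that check;
* δ¹⁸O isoscape: smooth equator-to-pole gradient (defaults 0.5 ‰ at the
  equator, −5 ‰ pole-ward drop, small zonal tilt 0.01 ‰/°) plus optional
  Gaussian coastal freshwater depressions;
* feathers: isoscape value at the bird's true origin cell + 1.6 ‰
  enrichment (C) or +13.0 ‰ discrimination (O) + a year effect (−0.15 ‰
  C, −0.5 ‰ O in the later year) + Gaussian analytical noise (0.10 ‰ C
  and δ¹⁵N, 0.50 ‰ O);
* groups: origins drawn from a bivariate Gaussian around a per-group
  center (rejection-sampled onto ocean cells), with per-group means for
  δ¹⁵N and the morphometrics so the tree can rediscover the grouping;
  sex is simulated with zero effect. Group centers default to grid-cell
  centers and the dispersion defaults to 1.0° — one grid cell — so that
  recovery tests measure assignment error rather than an arbitrary
  dispersion choice; with dispersion well above the map resolution the
  top-5 % region of a combined map no longer needs to contain the group
  centroid and coverage checks would test the generator, not the method.
* chlorophyll: constant background plus Gaussian hotspots; observations:
  cells sampled proportionally to a (non-negative) surface × effort
  field, jittered within-cell; eco-realms: named latitudinal bands
  partitioning the extent.

Everything is deterministic given the configuration seed.

What the generator does **not** emulate: ocean circulation or seasonality,
mechanistic plankton isotope models, realistic coastlines (land is a set
of rectangles), spatially correlated isoscape error (the SD layer is
constant), observation-effort geography, or ecologically realistic group
dispersions (real moulting ranges span ocean basins). Passing recovery
tests therefore show the machinery is correct and calibrated under its
stated assumptions, not that real moulting grounds can be recovered at
one-cell accuracy.

## Problem sizes used in the checks

The default grid is 70×100 cells at 1° (a southern-hemisphere Atlantic
window, 6 610 ocean cells). The acceptance script simulates groups of 19
and 185 birds (mirroring a small/large two-species study), 500 null
datasets of n = 100 for the tree's type-I rate, and 100 replicates of
15-bird groups for the 95 %-quantile origin-coverage rate; it completes in
a few seconds on one CPU.

## Known limitations

* Record-level reproduction of published storm-petrel results requires
  the original per-bird table; printed summary tables (means/SDs rounded
  to 0.1) reconstruct the species-split Welch t only to ~1 %, not printed
  precision. The pipeline accepts such a table as a column-mapped CSV.
* Asymptotic χ² node tests are slightly conservative in far tails at
  n ≈ 100; no permutation p-values are offered.
* The ESRI ASCII raster format carries no CRS; grids are assumed
  geographic lat/lon and anything else is rejected.
* `scale_surfaces(pooled_sd)` answers a different question than
  `per_layer` (cross-map comparability vs per-map shape); both are
  exposed because the aggregation convention is a genuine free choice.
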