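# Methods

## Model

Accessibility follows the two-step floating catchment area (2SFCA)
family with a truncated Gaussian distance-decay kernel. Demand points
are residential communities *i* with household counts *H_i*; supply
points are green spaces *j* with service capacity equal to their area
*S_j* in m². Within a catchment radius *d₀*, the kernel

G(d, d₀) = [exp(−½(d/d₀)²) − exp(−½)] / [1 − exp(−½)] for d ≤ d₀, else 0

weights interactions; it equals 1 at distance 0, decays smoothly, and
reaches exactly 0 at the boundary, so catchment membership (defined
boundary-inclusive, d ≤ d₀) and kernel support differ only on the
boundary itself, where the weight vanishes. Step 1 assigns each green
space a supply-to-demand ratio R_j = S_j / Σ_k G(d_kj, d₀)·H_k over the
communities in its catchment; step 2 gives each community
A_i = Σ_l G(d_il, d₀)·R_l, in m² of green space per household.

Assumptions: straight-line distance (great-circle for lon/lat on a
sphere of radius 6 371 000 m, Euclidean for projected planar meters) —
no road network or travel-time routing; green spaces act through their
centroid and total area; households are the unit of demand and every
household at a point is identical.

Two algebraic properties anchor the test suite. *Mass conservation*:
Σ_i H_i·A_i equals Σ S_j over green spaces whose catchment contains at
least one positively weighted community — the transform only
redistributes area. *Degenerate supply*: a green space whose catchment
is empty, or contains demand only exactly on the boundary, has an
undefined ratio; it is flagged unused (NaN) rather than infinite, and
contributes to no community because its kernel weight toward any such
community is zero anyway.

## Equity statistic

City equity is the household-weighted Gini coefficient of per-household
accessibility, each community forming one group. The grouped form

GC = Σ p_i y_i − 2 Σ (ΣP_i)′ y_i + 1,

with p_i the household share, y_i = H_i·A_i / Σ H·A the accessibility
mass share and (ΣP_i)′ the cumulative household share, returns the
classical nonnegative statistic only when groups are ordered by
*descending* per-household accessibility; we verified the descending
form agrees with the pairwise weighted mean-absolute-difference
definition and with 1 − 2·AUC of the grouped Lorenz curve to machine
precision, and that ordering is what the implementation uses. Levels
follow lower-inclusive bands: Good [0, 0.3), Normal [0.3, 0.4), Warning
[0.4, 0.6], Dangerous (0.6, 1); the tie at exactly 0.6 goes to Warning
because the Dangerous band is defined strictly greater.

Cities with zero total accessibility have no defined Gini and are
excluded with reason "zero accessibility"; cities with fewer than
`min_communities` (default 2) groups are excluded as "insufficient
groups", since a one-group Gini is vacuous. The minimum is
configurable because no principled universal value exists.

## Traditional accessibility and the ratio

The demand-blind baseline ("traditional" accessibility) exists in
three variants. The default, `per_household`, is 2SFCA with
cross-community competition removed: each reachable green space is
rated as if the community were its only user, in which case the kernel
cancels and A_trad_i = Σ_{l reachable} S_l / H_i. This choice makes
"one community per supply cluster" an exact identity with 2SFCA
(ratio ≡ 1), which the tests exploit, and shares units with A_i. Its
cost is one-sidedness: competition can only reduce access, so A_i ≤
A_trad_i and city ratios never exceed 1 under this variant. The
`decayed_per_household` variant (Σ G·S_l / H_i) keeps the kernel and
lets the city-level ratio straddle 1 — communities whose decayed
competition is lighter than their own weight come out ahead — which is
the variant the comparative ratio analysis and the acceptance script
use; `decayed_supply` (Σ G·S_l) drops household normalization
entirely. The chosen variant is recorded in the pipeline metadata.

City means of accessibility are unweighted over communities (an
"average community" level); household-weighted means are also emitted.
Group comparisons (total green area, mean house price between ratio>1
and ratio<1 cities) use Welch's unequal-variance two-sided t-test — the
robust default when group sizes and variances differ and no flavor is
otherwise dictated. Price tiers default to the fixed published bands
(edges 5 500, 7 640, 11 038, 23 902 yuan/m², edge values assigned to
the lower tier, matching contiguous printed bands); a quantile mode
cuts quintiles instead, for synthetic prices on a different scale.
Per-tier OLS of Gini on mean price reports slope, intercept and the
two-sided slope p-value, and declines to fit tiers with fewer than 3
cities or constant price.

## Synthetic data generator

The generator emulates the published per-city marginals of the kind of
national community/green-space dataset the analysis targets: green
spots per city Poisson around 33.06, communities per city Poisson
around 315.06, spot areas lognormal with mean 14.96 ha resampled to
stay ≥ 1 ha, and house prices around 16 368 yuan/m². Only the means are
targeted: the published dispersion figures for these marginals are
internally inconsistent (e.g. a standard deviation of 8 497 for spot
counts whose maximum is 1 220, apparently variances or misprints), so
distribution shapes — lognormal areas, households and prices, Poisson
counts — are the package's own choices of realistic heavy-tailed urban
marginals. Households per community are lognormal with median ≈ 800
(typical of Chinese commodity-housing estates; no published marginal
exists for this field).

Cities live on a planar square of side 20 km. Community layout is
uniform, monocentric (Gaussian around the center, sd = extent/6) or
clustered (a few Gaussian sub-centers). Green spots are uniform at
`green_cluster` = 0 and concentrate around a random focus with sd =
extent / (2·(1+γ_c)) as γ_c grows — raising the Gini, which the tests
check in the mean across seeds. Prices follow
price_base · exp(γ·z + ε), where z is the standardized decay-weighted
green proximity (kernel radius 2.5 km) and ε is N(0, 0.15²) log-noise;
γ = 0 decouples prices from green space, positive γ produces the
price–accessibility association the recovery tests detect. Degenerate
cities for exercising the exclusion rule are constructed explicitly:
their green spots are translated 50 km + extent away, beyond any
catchment, and their ids are returned so tests are deterministic.

What the generator does **not** emulate: real street networks and
travel times, irregular administrative boundaries, polygon green-space
geometry (spots are points with areas), spatially correlated household
sizes, and listing-data biases (web-crawled coverage skew). Passing
tests therefore demonstrate the statistical machinery and its
invariants, not conclusions about any real city system.

## Numerical choices

- Distances: haversine on R = 6 371 000 m; planar inputs use exact
  Euclidean distance. The source projection of real meter-based data is
  declared by the `planar` config flag rather than guessed.
- The 1 ha minimum green-space size is inclusive (≥ 1 ha), so datasets
  whose minimum is exactly 1 ha survive the filter.
- Unused supply ratios are NaN and propagate as zero contribution;
  accessibility values are finite and nonnegative by construction.
- Tiny negative Gini values from floating-point cancellation under
  perfect equality (|GC| < 1e−12) are clamped to 0.
- GeoJSON polygon areas for lon/lat input use a local equirectangular
  projection about the polygon centroid; adequate for park-sized
  features away from the poles.
- The grid-bucket spatial index is an optional accelerator whose
  radius queries are tested to return exactly the dense-scan result.
- Problem sizes in tests and the acceptance script (20-city countries,
  ≤ 500 communities per city, ≤ 200 random instances per property) are
  chosen to make the full suite run in seconds while still exercising
  every code path at realistic per-city scale.

## Known limitations

- Straight-line distance understates effective distance in cities with
  barriers (rivers, rail); network-based 2SFCA variants are out of
  scope.
- A single Gaussian kernel at four fixed radii; no multi-zone or
  gravity-exponent variants.
- The Gini is a global index per city; spatial autocorrelation of
  accessibility (e.g. Moran's I) is not computed.
- Per-tier OLS across cities is descriptive; no spatial-lag/error
  model, and no multiple-testing correction is applied to the
  per-radius test family.
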