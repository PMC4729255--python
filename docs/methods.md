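# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Assemblage trait metrics

Fruit-body size is d², the squared mean cap diameter in mm² — a biomass
index, not a literal area. The mean number of fruit bodies of a species is
its summed count divided by the number of occupied plots; by default this
is computed **pooled** over years (one trait value per species, used in
every year's analysis). A per-year mode (yearly sum / yearly occupancy) is
provided because either reading of "per occupied plot" is defensible for
multi-year data; pooled was chosen as the default since the nulls treat
the trait as a fixed species attribute.

Species on fewer than four distinct plots (counted **across** years) are
excluded: occupancy-1..3 species carry an unreliable count trait.
Both traits are log₁₀-transformed at the **species** level, then averaged
unweighted over the species present in a plot × guild × year assemblage.
Abundance never weights the mean — this is a species-mean, not a
community-weighted mean, so rare and dominant species count equally.

## Null models and SES

**Regional-pool null.** Richness-matched draws without replacement from
the guild's stratum of the regional trait pool; only fruit-body size is
scored this way (no regional count data exist, so the count metric is
restricted to the swap null and the API enforces that compatibility).
Default n_rand = 100 replicates.

**Independent swap (fixed–fixed) null.** The binary species × plot matrix
per guild and year is randomized by checkerboard swaps: a random row pair
and column pair is exchanged whenever its 2×2 submatrix is a diagonal or
anti-diagonal pattern, preserving all row and column sums exactly. Only
*successful* swaps are counted. The default chain uses a burn-in of
10 × fill and a thinning interval of 2 × fill successful swaps, where fill
is the number of presences — standard magnitudes for sequential swap
chains at this matrix size; both are configurable, and an independent
restart mode (fresh chain per replicate) is available. A matrix with no
swappable submatrix is returned unchanged after a bounded attempt budget
(10⁶ attempts per requested swap) with a warning. The known non-uniformity
of independent-swap sampling over the fixed-marginal class is not
corrected. The swap kernel is JIT-compiled with numba; chains of ~10⁶
successful swaps run in seconds.

**SES.** (observed − null mean) / null sd with the *sample* (n−1) standard
deviation — the difference from the population sd is negligible at
n_rand = 100 but is fixed for reproducibility. A constant null
(sd = 0, e.g. all species sharing one trait value) flags the SES undefined
rather than raising; undefined SES propagates as missing through the
regression stage. |SES| > 2 is the conventional significance band.

## Resource gradient

PCA of the eight stand variables on the correlation matrix (z-scored
columns, eigendecomposition). Scores are zero-mean by construction. Sign
conventions: PC1 is oriented so growing-stock volume loads positively
(large scores = resource-rich stands), PC2 so stand age loads positively
(large scores = old stands). Constant variables are dropped (correlation
undefined) and missing values mean-imputed, both with warnings.

## Mixed-effects regression

For each response metric (raw mean log size, raw mean log number, and the
three SES variants), one row per plot × guild × year:

y = Xβ + u_plot + ε,  u_plot ~ N(0, σ²_plot),  ε ~ N(0, σ²_guild)

Fixed effects: guild (reference ST), year as factor (reference = first
year), resource (PC1), age (PC2), guild × resource, guild × year. The
three-way guild × resource × year interaction is off by default, available
behind a flag. The residual variance differs by guild (the two guilds'
metrics have very different spread); the plot random intercept handles
repeated measurement.

Fitting maximizes the restricted likelihood over the three log-variance
parameters with bounded L-BFGS-B (Nelder-Mead fallback), with fixed
effects profiled out by GLS. The random-intercept-plus-diagonal structure
makes the marginal covariance block-diagonal by plot, so each REML
evaluation uses Woodbury identities on ≤ 6×6 blocks. Log-parameterization
keeps variances positive; bounds at e^±(10,30) relative to the response
variance keep the optimizer finite when a component is effectively zero.
Effects are summarized as z = estimate / SE against an expected mean of
zero; |z| > 1.96 / 2.58 / 3.29 are starred. The fit is cross-checked in
the test suite against an independent REML implementation (R nlme,
`lme` with `varIdent` guild weights) on simulated data.

The adjusted-R²-style summary is 1 − (1 − r²)(n − 1)/(n − p) with
r = corr(fixed-effect fitted values, observed); there is no canonical
definition for weighted mixed models, so ours is recorded in the report
metadata rather than treated as comparable across software.

## Synthetic-data model

The generator emulates a 48-plot, 3-year, two-guild inventory against a
conceptual pool of 300 species per guild:

- **Sizes**: log₁₀ d² ~ Normal per guild; defaults ECM mean 3.2, ST mean
  2.6, sd 0.5 — ECM fruit bodies roughly four times larger in median d²,
  spanning the realistic mm² range.
- **Trade-off**: log₁₀ characteristic count = 2.5 − b·log₁₀ size + ε
  (default b = 0.5, ε sd 0.3): bigger species produce fewer fruit bodies.
- **Occupancy skew**: base inclusion weights q ~ Beta(0.35, 8) — most
  species rare, a few widespread, giving ~10–25 species per plot per guild
  and ~200–250 species surviving the ≥4-plot filter.
- **Environment**: a latent resource axis r and an independent succession
  axis s, both standard normal per plot; growing-stock variables and upper
  canopy cover respond linearly to r, stand age and the lower tree layer
  to s, each with Gaussian noise. PC1/PC2 of the generated tables carry
  ~60% / ~23% of the variance and correlate > 0.95 with r and s. Values
  are not clipped, so extreme plots can exceed physical ranges (e.g.
  cover > 100%) in the far tails.
- **Filtering**: species s of guild g enters plot i (independently per
  year) with probability min(p_max, q_s · exp(−λ_g(r_i)(x_s − μ_g))),
  λ_g(r) = max(0, λ0_g − λ1_g·r). Defaults λ0 = {ECM: 0.5, ST: 2.5},
  λ1 = 0.5 for both: strong ST size filtering (ST assemblages far
  smaller-bodied than the pool), mild ECM filtering, both relaxing with
  resource availability so assemblage mean size rises and — through the
  trade-off — mean fruit-body number falls along the gradient.
- **Counts**: zero-truncated negative binomial around the characteristic
  count (dispersion 0.7), emulating the heavy right tail of real
  fruit-body counts.

Filtering acts on the pool → local-occurrence step; the swap null then
probes the residual trait–occurrence association within the realized
matrix (gradient-coupled filtering produces exactly such association).
Both effects are switchable via λ0 / λ1 per guild.

Not emulated: spatial autocorrelation between plots, within-season
phenology, host-tree identity, detection error, and year-to-year trait
correlation beyond the shared species pool. Passing tests therefore show
that the machinery recovers known structure of this generative family —
not that field inventories satisfy its assumptions.

## Determinism and problem sizes

Every stochastic stage draws from an RNG substream spawned from one master
seed; pipeline reruns with identical config + seed are bit-identical (the
run log records versions and counts, never timestamps). The acceptance
script runs the guild-contrast scenario at the full 48 × 3 design and the
gradient-recovery scenario at 32 plots with 150-species pools over 50
replicates — sizes chosen so the whole script completes in about a minute
while leaving the Monte-Carlo tolerances comfortable.

## Known limitations

- The independent swap samples the fixed-marginal class non-uniformly;
  no correction (e.g. trial-swap weighting) is applied.
- The regional-pool null ignores regional abundance: colonization
  probability is uniform within a stratum.
- SES values from n_rand = 100 have tail probabilities closer to a
  t(99) than a normal; the |SES| > 2 convention is applied as-is.
- The REML engine is specific to this design (one random intercept, one
  two-level variance group); it is not a general LMM implementation.
- Vegetation cover and stand variables are treated as plot-level
  covariates regardless of the differing sub-plot areas they would be
  measured on in the field.
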