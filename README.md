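# sporocarp

Trait-based null-model analysis of macrofungal fruit-body assemblages along
forest resource gradients.

## The problem

Macrofungi face a reproductive allocation trade-off: produce few large
fruit bodies or many small ones. Whether local assemblages are a random
draw from the regional species pool with respect to these reproductive
traits — or filtered by the local carbon supply — is a community-assembly
question that differs between trophic guilds. Ectomycorrhizal (ECM) fungi
draw carbon from host trees; saprotrophic (ST) fungi depend on dead organic
matter, so their reproduction should track local resource availability much
more tightly.

`sporocarp` implements the full inferential chain for multi-year
plot-based fruit-body inventories:

1. **Species traits.** Fruit-body size is indexed as d², the squared mean
   cap diameter (mm²), a standard biomass proxy; the mean number of fruit
   bodies per species is the total count divided by the number of occupied
   plots. Species on fewer than four plots are excluded. Both traits are
   log₁₀-transformed at the species level.
2. **Assemblage means.** For each plot × guild × year, the unweighted mean
   of the species' log-traits over the species present.
3. **Regional-pool null.** For a plot of richness S, draw S species without
   replacement from the guild's stratum of a regional trait pool, repeat
   n = 100 times, and compute the standardized effect size
   SES = (obs − mean_null) / sd_null. |SES| > 2 flags deviation.
4. **Local swap null (fixed–fixed).** Randomize the binary species × plot
   matrix with the independent swap algorithm — 2×2 checkerboard exchanges
   that exactly preserve species occupancies and plot richness — and score
   both size and fruit-body number against the swap distribution. This
   null is immune to richness artefacts.
5. **Gradient regression.** Stand variables (growing stock, basal area,
   DBH, cover layers, stand age) are reduced by PCA on the correlation
   matrix; PC1 is the resource-availability axis, PC2 the stand-age axis.
   Raw and SES metrics are regressed on resource, age, year (factor),
   guild, and guild interactions with a plot random intercept and
   guild-specific residual variances (REML); effects are reported as
   z = estimate / SE.

A synthetic-data generator produces inventories with the assumed structure
(two guilds with lognormal size distributions and ECM > ST, a size–number
trade-off, occupancy skew, and gradient-coupled size filtering), so every
stage is testable without field data.

## Worked example

```bash
sporocarp simulate --out data --seed 42
sporocarp run-all --communities data/communities.csv --traits data/traits.csv \
    --pool data/pool.csv --environment data/environment.csv --out results --seed 7
```

The run log reports the funnel: 5084 records and 380 observed species
loaded, 222 species retained by the ≥4-plot filter, 288 plot/guild/year
assemblage rows, 864 SES rows, PC variance fractions 0.601 / 0.232.

Under the default generator (strong ST size filtering, mild ECM
filtering), the regional-pool SES of mean fruit-body size separates the
guilds exactly as intended — ST assemblages are far smaller-bodied than a
random pool draw, ECM assemblages mostly are not:

| guild | mean SES | sd   | % plot-years < −2 |
|-------|---------:|-----:|------------------:|
| ECM   | −1.15    | 1.09 | 22.2              |
| ST    | −5.62    | 1.23 | 100.0             |

The mixed models recover the gradient: the resource (PC1) coefficient for
each response (z = estimate/SE):

| response            | estimate |    se |      z |
|---------------------|---------:|------:|-------:|
| raw mean log size   |    0.023 | 0.003 |   7.84 |
| raw mean log number |   −0.016 | 0.003 |  −5.50 |
| SES size (regional) |    0.415 | 0.033 |  12.76 |
| SES size (local)    |    0.543 | 0.041 |  13.28 |
| SES number (local)  |   −0.391 | 0.039 |  −9.96 |

Mean fruit-body size increases and mean fruit-body number decreases with
resource availability, in raw means and in both null-model effect sizes.

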