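# seastab

Do marine protected areas (MPAs) buffer seagrass fish communities against
monsoon-season variability?  `seastab` is an analysis toolkit for
repeated underwater-visual-census surveys of seagrass-associated fish
inside and outside MPAs: a handful of sites, each surveyed with belt
transects across the short-rains / long-rains / dry seasonal cycle.  It
is written for community ecologists who want the full inferential chain —
from raw transect rows to trajectory-stability metrics and causal path
models — as tested, scriptable Python instead of an ad-hoc R session.

## What it computes

Given long-format fish and seagrass-cover tables (one row per observed
fish; six cover quadrats per 25 × 4 m transect), the package runs four
linked analyses per age class (total / juvenile / subadult / adult,
staged from 5-cm length estimates):

1. **Univariate mixed models.** Densities (√-transformed), species
   richness *S* and Shannon *H′* = −Σ pᵢ ln pᵢ are modelled as
   `y ~ season × management + (1 | site)`, fitted by REML with marginal
   (Type III) F tests, Satterthwaite denominator df, likelihood-ratio
   tests against the random-effects-only null, marginal/conditional R²
   (σ²f /(σ²f + σ²site + σ²res) and (σ²f + σ²site)/(…)), Tukey all-pair
   season contrasts, and VIF screening.
2. **Community structure.** Bray–Curtis dissimilarities
   d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on site-level communities;
   PERMANOVA with sequential sums of squares and permutations
   constrained within sites (strata); SIMPER species contributions.
3. **Trajectory stability.** Non-metric MDS (Kruskal stress-1, isotonic
   regression + Guttman updates) embeds each site × season community;
   per site, four temporal-variability metrics are taken from its
   seasonal trajectory — polygon (convex-hull) area, range (max pairwise
   distance), mean distance to centroid, mean consecutive-season step —
   and compared between management levels (Welch + exact permutation
   over site relabelings; the mixed model prescribed for this design is
   unidentifiable with one value per site and is reported as such).
4. **Mechanisms.** Piecewise structural equation models
   (season → seagrass cover → fish density, with season as a composite
   three-level factor), each node a site-random-intercept mixed model;
   d-separation basis-set tests combined by Fisher's
   C = −2 Σ ln pᵢ ~ χ²₂ₖ.  Plus pairwise species-density slopes per
   management level and a paired t-test for synchrony vs compensation.

Because raw survey data of this kind are rarely deposited, the package
ships a first-class synthetic survey generator (negative-binomial
species counts; seasonal forcing; cover-mediated density; an optional
management-dependent synchronous "fishing" perturbation) whose
closed-form expectations give every analysis a recoverable ground truth.

## Worked example

```python
import seastab as st

cfg = st.GeneratorConfig.default(seed=42)
records = st.generate_survey(cfg)
print(f"{len(records)} transects surveyed")

site = st.aggregate_density(records, level="site", aggregation="sum")
d = st.bray_curtis(site)
res = st.Permanova(d, site.sample_info, strata="site").fit(n_perm=999, seed=1)
print(res.summary())

ordn = st.nmds(d, seed=1)
metrics = st.stability_by_site(ordn.coords, site.sample_info)
print(st.compare_stability(metrics).table[
    ["mean_MPA", "mean_open", "estimate", "perm_p"]].round(4))
```

prints

```
111 transects surveyed
PERMANOVA (sequential SS, Bray-Curtis)
permutations: 999, constrained within strata (site)

                   df  SumOfSqs     R2      F      p
term
season              2    0.1615 0.2743 3.0140 0.0220
management          1    0.1375 0.2336 5.1340 0.0710
season:management   2    0.1289 0.2190 2.4062 0.1380
Residual            6    0.1607 0.2730    NaN    NaN
Total              11    0.5886 1.0000    NaN    NaN
                  mean_MPA  mean_open  estimate  perm_p
metric
area                0.0000     0.0003    0.0003  0.3333
range               0.0168     0.0441    0.0273  0.3333
dist_centroid       0.0065     0.0189    0.0124  0.3333
dist_consecutive    0.0126     0.0268    0.0142  0.3333
```

Read this as: the simulated 111-transect survey shows a seasonal shift in
community structure (PERMANOVA p = 0.022 with permutations kept within
sites), and every trajectory-variability metric is larger at the fished
sites — the generator's built-in instability contrast — though with only
four sites the exact permutation test bottoms out at p = 2/6 ≈ 0.33.

The full pipeline (all four age classes, SEM, synchrony, manifest with
checksums) runs from the shell:

```bash
seastab simulate --seed 7 --out survey/
seastab analyze --fish survey/fish.csv --cover survey/cover.csv \
    --species survey/species.csv --seed 7 --out results/
seastab report --analysis-dir results/
```

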