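# Methods

This note documents the statistical procedures implemented in `seastab`,
the synthetic-data model behind its tests, and the numerical and design
choices a maintainer should know about.

## Survey data model

The sampling unit is a 25 × 4 m (100 m²) belt transect inside a seagrass
bed, surveyed by underwater visual census.  Densities are expressed per
100 m², so on the default transect the density equals the raw count;
transects of other areas are rescaled.  Seagrass cover is the mean of
six quadrat estimates recorded to the nearest 10%.  The default study
layout is four sites — two inside MPAs (10 and 7 transects), two fished
(10 each) — revisited in three monsoon seasons (short rains SR, long
rains LR, dry D), i.e. (10+10+10+7) × 3 = 111 transect records, split 51
(MPA) / 60 (open) across management levels.

**Age classes.** Fish lengths are recorded on a 5-cm grid.  Published
stage tables are not generally available per species, so the default
staging uses fractions of the species' maximum length: juvenile below
Lmax/3, subadult in [Lmax/3, 2·Lmax/3), adult above, with half-open
intervals so boundary lengths go to the upper class (determinism).
Explicit per-species cut-points override this.  The species table
(`species,family,functional_group,lmax_cm[,cut1_cm,cut2_cm]`) carries
the inputs.  Age-class-filtered density tables keep the full species set
so matrices remain conformable; the three class tables sum cell-wise to
the all-ages table.

## Univariate responses and mixed models

Densities are √-transformed; all responses are then z-standardized over
the whole set of transects (population SD), making coefficients
comparable across responses.  Models are

    y ~ season * management + (1 | site)

"Site nested within management" reduces to a plain site random intercept
because site labels are unique across management levels.

The fitter profiles the single variance ratio λ = σ²site/σ²res out of
the REML (or ML) criterion and solves a bounded one-dimensional search
(log-λ in [−14, 14], with the λ = 0 boundary checked explicitly), so a
fit costs a few dozen closed-form per-group evaluations and Monte-Carlo
studies with thousands of fits are cheap.  Against `lme4::lmer` /
`lmerTest` on identical data the variance components, Type III F
statistics, Satterthwaite denominator df and Tukey p-values agree to the
fourth decimal.

* **F tests** are marginal (Type III), obtained from sum-to-zero coding
  so each term's own columns carry its hypothesis.  Denominator df use
  the Satterthwaite approximation: the variance of a contrast l′β is
  differentiated (finite differences) with respect to
  θ = (σ²site, σ²res), and the θ covariance comes from the
  finite-difference Hessian of the (restricted) log-likelihood.
  Multi-df terms combine eigencontrast dfs as
  df = 2E/(E−q), E = Σ νₘ/(νₘ−2).  A `ddf="residual"` fallback
  (n − rank) is available and is also used automatically when the site
  variance sits on the boundary (Satterthwaite undefined there).
* **Likelihood-ratio tests** compare ML fits of the full fixed structure
  against the random-effects-only null; χ² = 2Δℓ with df equal to the
  fixed-parameter difference.  Under null simulations on the survey
  design the test holds its 5% level (acceptance suite).
* **R²** follows the variance-partition convention for mixed models:
  marginal = var(Xβ̂)/(var(Xβ̂)+σ²site+σ²res); conditional adds σ²site
  to the numerator.
* **Tukey all-pair comparisons** are single-step adjustments of
  estimated marginal means (predictions averaged over the levels of the
  other factors; continuous covariates at their mean; `within=` pins a
  factor level when dissecting an interaction).  When the contrast
  correlation matrix is the balanced exchangeable pattern (|r| = 0.5,
  equal dfs) the adjusted p is the studentized-range tail probability —
  exact; otherwise a multivariate-t Monte-Carlo with a fixed internal
  seed (200 000 draws) is used.
* Deterministic (zero-residual) responses are handled by flooring the
  profiled residual variance at 1e−24·n·var(y), which leaves regular
  fits untouched; estimates remain exact, p-values degenerate to 0/1 as
  appropriate.

## Community structure

**Bray–Curtis** d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ); a pair of all-zero samples
is defined as d = 0 so that age-class filtering cannot produce NaNs.

**PERMANOVA** partitions the Gower-centred inner-product matrix
G = −½ J D² J by sequential (Type I) sums of squares in the order
season, management, season × management (configurable): SS for a term is
tr(H G) of the cumulative design hat matrix minus the previous
cumulative SS; pseudo-F uses the residual mean square.  p-values use the
(1+exceedances)/(1+n_perm) estimator, so p is never 0.  Permutations
shuffle sample labels; with `strata="site"` each site's samples are
shuffled only among themselves, respecting the repeated-measures design
(each site appears in all seasons).  The one-factor statistic matches
the classical distance-based sums-of-squares formula and
`scikit-bio`'s PERMANOVA; Monte-Carlo p converges to the exactly
enumerated p on small instances.

**SIMPER** attributes the mean between-group Bray–Curtis to species:
contributionᵢ = mean over between-group sample pairs of
|xᵢ−yᵢ|/Σₖ(xₖ+yₖ).  Contributions are nonnegative and sum exactly to
the mean between-group dissimilarity; an optional per-species
permutation p tests contribution against random group assignment.

**nMDS** minimizes Kruskal stress-1,
√(Σ(d−d̂)²/Σd²), alternating isotonic regression of configuration
distances on the input dissimilarities with a Guttman transform
(nonmetric SMACOF).  Stress-1 is evaluated after every iteration and
iteration stops as soon as it fails to decrease by `tol`, so the
recorded stress path is non-increasing by construction.  Defaults:
k = 2, 20 restarts (first initialized from the metric
principal-coordinate solution, the rest random Gaussian),
max 300 iterations, tol 1e−7 — conventional settings for ecological
ordination at this sample size.  Exactly embeddable configurations
reach stress < 1e−3 with perfect rank-order agreement.

## Trajectory-stability metrics

Each site contributes one ordination point per season (site-level
communities are the per-site, per-season sums of transect counts).  Per
site: **area** = convex-hull area of the seasonal points (the triangle
for three seasons; the hull generalizes it to any season count; 0 when
degenerate); **range** = maximum pairwise distance; **dist_centroid** =
mean distance to the arithmetic centroid; **dist_consecutive** = mean
step length in chronological order SR → LR → D, no wrap-around.  All are
invariant to rotation/reflection/translation of the ordination; scaling
coordinates by c scales the distances by c and the area by c².

**Management comparison.** The natural mixed model (metric ~ management
+ (1|site)) is unidentifiable here: with one metric value per site the
site intercept and the residual are not separable.  The model attempt is
reported with that tag, and inference rests on (a) a Welch two-sample
comparison across site values and (b) an exact two-sided permutation
test enumerating all reassignments of the management labels to sites
(6 arrangements for the 2+2 design, so the attainable minimum two-sided
p is 2/6).  The permutation p is the default inferential surface.

## Piecewise SEM

Causal hypotheses are DAGs over season (a three-level composite factor,
always exogenous), seagrass cover and a fish response.  Each endogenous
node is fitted as a site-random-intercept mixed model on its parents.
Season enters as its two sum-coded dummy columns and is tested jointly
(F test); its per-dummy coefficients are reported but flagged
sign-uninterpretable.  Continuous paths report standardized coefficients
coef·sd(x)/sd(y).

The testable implications form the d-separation basis set: one claim per
non-adjacent pair, the causally later variable regressed on the earlier
plus the union of both parents' sets (deduplicated; lexicographic
topological order makes the output independent of node listing).  Claim
p-values combine into Fisher's C = −2Σ ln pᵢ ~ χ² with 2k df; the model
is retained when p(C) > 0.05.  Claim p-values of exactly 0 are floored
at 1e−300 with a warning.  Interaction-bearing global models are handled
by the management split: separate MPA and open-access fits.

## Synchrony

On site-level **mean** densities (one value per species, site and
season), every unordered pair of species observed in both management
levels gets a slope: the alphabetically later species regressed on the
earlier one with a site random intercept (OLS fallback, tagged, when the
site variance is zero or the fit singular; zero-variance predictors are
excluded and logged).  The mean slopes of the two management levels are
compared by a paired t-test over the common pairs (df = n_pairs − 1).
All-zero differences give t = 0, p = 1; nonzero constant differences are
degenerate and reported as such.  Because "slope of correlation" is
ambiguous in parts of the literature, a Pearson-correlation variant is
available via `statistic="correlation"`; slopes are the default.  Note
the paired test treats pairs as exchangeable units; pairs sharing a
species are not independent, which the null-calibration test monitors
empirically (the realized type-I error stays within the binomial band).

## Synthetic survey generator

Per-species counts on a transect are negative binomial (dispersion
θ = 2, moderate overdispersion typical of schooling fish) with

    log μ = α_k + site_s + season_{k,t} + β_k · z(cover) + φ_M · f(t)

* α_k ~ N(0, 1): baseline log densities (a lognormal-ish species
  abundance distribution; ~40 species give ≈ 50–80 fish per transect,
  the magnitude of real seagrass UVC surveys);
* site effects N(0, 0.3); per-species seasonal responses N(0, 0.15),
  centred within species;
* cover: quadrat values are beta-distributed (concentration 30) around
  the site mean (55–75%) plus a management-scaled seasonal deviation
  (amplitude 3 pp inside MPAs, 12 pp outside; season shape (+1, −1, 0)
  over (SR, LR, D)), rounded to the nearest 10% and clipped — the field
  recording resolution.  Cover enters the fish model centred by fixed
  constants (65, 15), not by the realized sample moments, so
  expectations stay closed-form;
* β_k ~ N(0.3, 0.1): seagrass affinity;
* φ_M · f(t): a synchronous perturbation common to all species,
  f = (+1, 0, −1) over (SR, LR, D) — fishing pressure above average in
  the short rains and suppressed in the wind-limited dry season, applied
  unselectively (all species alike).  Default φ = 0.4 outside MPAs, 0
  inside.  Its magnitude is a calibration knob, not an estimate: no
  quantitative seasonal fishing-pressure data back it.

Lengths are drawn per fish from the species' age-class band on the 5-cm
grid with class mix (0.28, 0.40, 0.32) (juvenile/subadult/adult shares
of the order seen in the field); Lmax per species is 30, 45 or 60 cm so
every band contains at least one grid value.  Each site × season ×
transect cell has its own deterministic substream of the root seed, so
surveys are bit-reproducible and partially regenerable.

`ground_truth()` returns the exact NB means evaluated at the
deterministic seasonal cover mean; the quadrat-level cover noise adds a
Jensen term of order (β·σ_z)²/2 ≈ 0.3% at the defaults, which is inside
the Monte-Carlo tolerance the tests use.

**Named scenarios.** `default()` carries the documented contrast
(φ_open > 0, larger cover amplitude outside MPAs): fished communities
are less temporally stable, pair slopes more positive.
`mediation_scenario()` zeroes the direct seasonal channels (species
seasonal responses and φ) and keeps only the cover-mediated one — the
data-generating topology whose recovery (significant cover → fish path,
non-significant direct season claim) the acceptance suite checks.
`null_scenario()` removes all seasonal structure, for type-I-error
calibration.  `full_scale()` grows the community to 116 taxa in 33
families; the desk-scale default is 40 species in 11 families, which
keeps replicate studies (hundreds of surveys) in the minutes range while
preserving the design's dimensions (111 transects, 12 site-level
samples).

**What the generator does not emulate:** spatial structure within
sites, species interactions, observation biases of visual census
(detectability, length mis-estimation), recruitment pulses, or temporal
autocorrelation beyond the three-season cycle.  Passing tests therefore
show that the estimators recover the stated generative structure at
field-realistic sizes — not that real surveys satisfy these models.

## Problem sizes and seeds

Replicate studies use the package's documented desk-scale settings: 500
null replicates for calibration (PERMANOVA on 12-sample instances with
99 permutations; LRT on the 111-transect design; the paired slope test
on a 6-species community), 200 replicates for the contrast-recovery
checks (nMDS with 4 restarts, tol 1e−6, inside the replicate loop), and
analytic or ≤10-sample instances for all oracle comparisons.  Every
stochastic stage takes an explicit seed; the pipeline fans a single root
seed out per stage (CRC-mixed, < 2³¹) and records it in the manifest,
and reruns are verified bit-identical by checksum.

## Known limitations

* Satterthwaite dfs rely on finite-difference derivatives; near the
  σ²site = 0 boundary they fall back to residual dfs.
* The exact permutation test over four sites cannot reach p < 1/3; more
  sites are needed for sharper stability inference (a limitation of the
  design, not the implementation).
* SIMPER permutation p-values are computed per species without
  multiplicity adjustment.
* The nMDS early stop keeps the best iterate; on pathological inputs
  this may end before a local minimum (flagged via `converged`).
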