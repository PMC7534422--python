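# Methods

## Scope

`squashgs` re-implements, as a tested library, the statistical workflow of a
small genomic-selection program for fruit quality in a biparental winter
squash population: quantitative-genetic parameter estimation from repeated
fruit measurements, uni- and multi-trait GBLUP, index selection over
recurrent cycles, cross-validation of predictive ability, and realized-gain
analysis.  Because the real program's raw data are not required, a
first-class synthetic-data module generates populations with the same
statistical structure, and every claim the test suite makes is a claim about
recovery of known simulated truth, not about any particular field dataset.

## Models

### Repeatability model

For fruit-level records of one trait,

    y = X b + Z u + Z p + e,     u ~ N(0, sigma_u^2 K),
                                 p ~ N(0, sigma_p^2 I),   e ~ N(0, sigma_e^2 I)

with `X` holding an intercept and fixed environment (site) contrasts, `Z`
mapping fruit to plants, `K` the VanRaden genomic relationship matrix, `u`
additive genetic values and `p` the permanent-environment effect shared by
all fruit of a plant.  Repeatability and narrow-sense heritability follow as

    t  = (sigma_u^2 + sigma_p^2) / (sigma_u^2 + sigma_p^2 + sigma_e^2)
    h2 =  sigma_u^2              / (sigma_u^2 + sigma_p^2 + sigma_e^2)

The accuracy gain from averaging n fruit is `Delta_r = sqrt(1/(t + (1-t)/n))`
(the source formula's radical is typographically lost; only the rooted form
satisfies Delta_r(1) = 1 and is an accuracy ratio, so that reading is
implemented, with the un-rooted variance ratio behind `radical=False`).
`PAmax = sqrt(h2)` benchmarks genomic predictive ability against phenotypic
mass selection.  Record weights for heterogeneous error variance are
`w = (1-h2) / (c h2 + (1+(n-1)t)/n - h2)`, again a reading of a
typeset-damaged source formula chosen so that w > 0 and w is decreasing in
the marker-captured variance proportion c.

### Multi-trait GBLUP

    y = X b + Z u + e,   u ~ N(0, K ⊗ G),   e ~ N(0, I ⊗ R)

with per-trait fixed environment effects and unstructured (or, for the null
model of the genetic-covariance LRT, diagonal) G.  Responses are plant means
of the fruit records.  This is a deliberate design choice: fitting
fruit-level records without a permanent-environment term differs from the
plant-mean fit only through the 4-6-fruit variation in residual weighting,
a second-order effect, while plant means keep the fit exact under the
canonical rotation below.  Genetic correlations are
`r_g = G_ij / sqrt(G_ii G_jj)`; their significance is the likelihood-ratio
test of unstructured versus diagonal G (chi-square, df = number of freed
covariances), Bonferroni-adjusted over the trait pairs tested in a run.

### Selection indices

Smith-Hazel coefficients are `b = P^-1 G a`.  Within the program, selection
uses the equal-weight GEBV index `I = sum_t GEBV_t` over the three quality
traits; in gain trials, where candidates carry phenotypes but no marker
data, the Smith-Hazel weights are applied to phenotypes instead.  Index
heritability is `h2_I = (b'Gb)/(b'Pb)`.

### Realized gain

Gain trials are modeled as

    y = mu + site + block(site) + plot(block) + c * cycle + e

with random site, per-site block variances, plot effects only at sites with
intra-block replication, a fixed numeric cycle covariate (default codes
1, 2, 3, 5 — the gap reflects an untested cycle), and residual variances
grouped by harvesting method.  The slope on `cycle` is the average gain per
selection cycle; its test is a Wald F with containment denominator degrees
of freedom `n - rank(X) - (total random-effect levels)`.  Interpretation
note: with plot-mean responses, a plot effect at a site with one record per
plot would be confounded with the residual, so "intra-block replication" is
represented as two sub-plot records sharing a plot effect at the flagged
sites.

## REML estimation

All variance components are estimated by EM-REML: updates keep every
component non-negative (G and R inside the PSD cone) and the restricted
log-likelihood non-decreasing, which the tests assert directly.  Because EM
crawls near an optimum, steps are extrapolated in log-parameter space
(SQUAREM-style) with a safeguard that accepts an extrapolated point only if
its restricted log-likelihood is at least that of the plain double-EM step;
the recorded likelihood history therefore stays monotone and the fixed
point is untouched.  Convergence is declared at |Δ log-lik| < 1e-8 (cap
1000 iterations, non-convergence flagged, never silent); when an estimate
is pinned to a boundary — a variance at the 1e-10 floor, or G held on the
PSD cone by eigenvalue bending at 1e-6 × trace — the likelihood can creep
indefinitely, so parameter stability (max update below ~1e-9 on the data's
variance scale) is an additional convergence criterion and multi-trait fits
carry an `at_boundary` flag.  Estimates at the floor are reported as 0.

Two exact structural reductions keep the stated problem sizes fast:

* the repeatability model is fitted on plant means with residual variance
  `sigma_e^2 / n_i`, plus the within-plant sum of squares entering the
  likelihood analytically (within-plant contrasts are free of fixed and
  plant-level effects), so an 800-plant, 4000-record fit works with
  800 x 800 matrices;
* multi-trait fits rotate onto the eigenbasis of K, making each iteration
  batched T x T operations (T = 2 or 3 traits).

For single-genetic-component GBLUP without repeated measures, the variance
ratio is profiled out on the eigenbasis of K and optimized by a coarse grid
plus Brent refinement; this profiled solver is the default for that model
class and agrees with generic EM to 1e-4 in the heritability (asserted on
random instances and against a brute-force restricted-likelihood grid
computed via error contrasts, a route independent of the EM code).

Fixed designs are reduced to full rank by pivoted QR with a logged warning;
multi-trait fits drop plants missing any trait (logged); aliasing of the
permanent-environment and residual variances (every plant measured once) is
an error directing the caller to plain GBLUP.

## Synthetic data

The generator mimics the study system it stands in for:

* **Population.**  Two fully inbred founders carrying opposite alleles at
  every marker; F1 selfed to an F2 base population (default 200 plants);
  later generations by random mating of selected plants, each dam's fruit
  pollinated by 4 random sires (selfing excluded, seed-level sire drawn
  uniformly from the pool, progeny counts balanced across half-sib
  families).  Meiosis is Haldane: Poisson crossover counts on the map
  length, uniform positions, no interference.  Default map: 20 chromosomes
  x 100 cM, 60 markers each.
* **Traits.**  Additive effects multivariate normal across traits with a
  target genetic-correlation matrix, all markers causal by default
  (infinitesimal-style; `n_qtl` restricts).  Effects are rescaled so the
  variance of true breeding values under the exact F2 dosage law equals the
  target: `Var(u) = b' S b` with `S_jk = (1-2c_jk)/2` from the Haldane map.
  The coupling-phase LD term matters — the genic (linkage-equilibrium)
  formula alone under-delivers realized heritability by ~30% on dense maps.
  Total phenotypic variance is normalized to 1 per trait so
  `sigma_u^2 = h2`, `sigma_p^2 = t - h2`, `sigma_e^2 = 1 - t` are exact.
  Defaults pattern the study's estimates: index traits (Brix, percent dry
  matter, flesh color a*) at h2 = (0.10, 0.13, 0.23), t = (0.45, 0.51,
  0.62), quality-quality genetic correlations up to 0.93, a yield trait at
  h2 = 0.12 unfavorably correlated with quality.
* **Records.**  Each plant grows at one site (fixed site shifts, default
  SD 0.5 on the unit-variance trait scale); 4-6 fruit per plant (uniform;
  the source reports only that 4-6 fruit suffice, so the range is a config
  default, not a claim of fidelity); yield traits recorded once per plant
  with the permanent-environment and fruit variances collapsed so h2 stays
  on target.
* **GBS noise.**  Per-call depths Poisson(7); calls below depth 2 missing;
  5% extra uniform dropout; below depth 7 a heterozygote is miscalled
  homozygous with probability 2·(1/2)^depth (allele sampling), split evenly
  between the homozygotes.  Depth 7 is where a two-read heterozygote call
  is effectively guaranteed, which is why the error model switches off
  there.

What the generator does **not** emulate: dominance and epistasis, G×E
(sites shift means only), sequence-level artifacts (allelic dropout by
restriction-site polymorphism, paralog collapse), selective genotyping, or
pedigree errors.  Passing tests therefore demonstrate that the estimators
and the selection machinery recover truth under the stated additive,
single-environment-effect model — not that real squash data meet those
assumptions.

## Genotype QC and the relationship matrix

Depth masking precedes frequency filters.  `qc_filter` order is fixed:
individuals above 40% missingness are dropped first, marker statistics are
recomputed, then markers above 20% missingness or below 5% MAF are dropped;
two profiles carry the defaults of the two genotyping contexts
(`selection_pipeline`: depth >= 2; `cv_pipeline`: depth >= 7, 50% marker
missingness tolerated — the source uses both without reconciling them, so
both are exposed as the same parameters with different defaults).  The
parent-informed filter keeps markers homozygous within and polymorphic
between the founders, with <= 50% missingness and < 90% heterozygosity.
Marker sets merge on common marker ids in the first set's order.  Remaining
missing calls are mean imputed — one deterministic, testable method (the
original workflow mixed EM-based and LD-kNNi imputation with mean
imputation as the fallback; standardizing on the fallback is a documented
deviation).  The GRM is VanRaden method 1, `K = WW'/(2 Σ p(1-p))` with
observed allele frequencies; in a large F2 the mean diagonal is near 1.

## Selection scheme driver

`run_recurrent_gs` executes: base-population phenotypic selection by
independent culling (top 20% for every quality trait, inclusive type-7
quantile thresholds, and not in the bottom 50% for yield); where fewer
plants qualify than the 10% target, the driver tops up by mean within-trait
rank — the source picked an exact count without stating an algorithm, and
with three jointly-required top-20% rules the expected eligible count is
below the target in most draws.  GS cycles then select the top 10% on the
equal-weight GEBV index from MT-GBLUP, with the model trained at field
generations (cycles 0 and 2 by default) and each cycle's candidates scored
by the newest model trained strictly earlier (the cycle-2 candidates are
scored by the cycle-0 model, mirroring the genotyping lag in the original
scheme).  Candidate GEBVs come from a joint GRM over training and candidate
genotypes after QC and imputation.  The driver tracks the mean true index
breeding value per generation, which the tests require to increase in every
GS cycle in >= 90% of seeds, with a fraction-1.0 (no-selection) control
showing pure drift.

## Cross-validation

Within-set CV: repeated 80/20 splits (default 50), identical partitions
across traits, truth = plant means, PA = Pearson(GEBV, truth) on the masked
fold; undefined correlations (constant folds) are recorded as missing and
excluded from summaries, never imputed.  Across-set CV: one GRM on the
merged marker set (single joint-K prediction, chosen over separate-K
equations as the standard, simpler-to-verify route), train on one
population, predict the other.  Stratified CV: equal draws per set form the
training composite, 25 per set are tested, sweeping the training size.  All
schemes are bit-reproducible under a fixed seed.

## Numerical choices and conventions

* Variance floor 1e-10; floor-level estimates reported as 0.
* PSD bending: eigenvalues clipped at 1e-6 × trace.
* Selection ties broken by ascending individual id; `ceil(fraction × n)`
  selected.
* Culling thresholds: type-7 (linear-interpolation) quantiles, inclusive.
* Printed parameter tables round half-up to 2 decimals.
* Bonferroni m = number of pairs tested in the invocation, logged.
* Missing dosage sentinel -1 (the VCFtools `--012` dialect); multi-allelic
  VCF records are skipped with a logged count at ingestion.
* One global seed; independent child streams per operation via fixed
  spawn-key offsets, so stage re-ordering cannot silently change results.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` use the study's scales where the
check depends on them (800 plants × 5 fruit for parameter recovery, 200
null simulations for type-I error, 20 seeds for stochastic criteria) and
smaller populations (150-400 plants) where only the mechanics are under
test; each file states its sizes inline.

## Known limitations

* Wald denominator df uses the containment approximation; the original
  software's algebraic df computation is out of scope, and the type-I
  checks show the approximation runs near the upper half of the nominal
  band on small trials.
* The LRT for a genetic covariance is boundary-affected (G constrained
  PSD), hence conservative; the null rejection rate sits below 5%.
* No standard errors on h2 and t (point estimates validated by
  simulation); no Bayesian whole-genome regressions, dominance, spatial
  models or explicit G×E terms.
* `mt_reml_fit` supports 2-3 traits (bivariate correlations and the
  three-trait index model), not arbitrary trait counts.
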