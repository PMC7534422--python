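# squashgs

Genomic prediction and multi-trait genomic selection for biparental
fruit-crop breeding populations, built around the workflow of a small winter
squash (*Cucurbita moschata*) program: repeated fruit measurements on a few
hundred plants, sparse genotyping-by-sequencing markers, and selection on an
index of fruit-quality traits.

It is aimed at breeders and quantitative geneticists who want to estimate
trait parameters, predict breeding values and evaluate recurrent genomic
selection **without** commercial mixed-model software, and at methodologists
who want a fully synthetic, seeded test bed for the whole pipeline.

## What it computes

* **Repeatability model** `y = Xb + Zu + Zp + e` with `u ~ N(0, σ²ᵤK)` and a
  permanent-environment effect `p` for repeated fruit on one plant, giving
  repeatability `t = (σ²ᵤ+σ²ₚ)/(σ²ᵤ+σ²ₚ+σ²ₑ)`, narrow-sense heritability
  `h² = σ²ᵤ/(σ²ᵤ+σ²ₚ+σ²ₑ)`, the accuracy gain from n fruit
  `Δr = √(1/(t+(1−t)/n))`, and the phenotypic-selection benchmark
  `PAmax = √h²`.
* **Multi-trait GBLUP** `μ ~ N(0, K⊗G)`, `e ~ N(0, I⊗R)` by EM-REML with
  unstructured or diagonal G, genetic correlations `r_g = G₁₂/√(G₁₁G₂₂)`
  with likelihood-ratio tests, and GEBVs for genotyped-but-unphenotyped
  selection candidates.
* **Selection**: Smith–Hazel weights `b = P⁻¹Ga`, the equal-weight GEBV
  index, truncation and independent-culling rules, and a driver that runs
  phenotypic culling plus recurrent genomic selection on synthetic
  populations.
* **Evaluation**: within-set / across-set / stratified cross-validation of
  predictive ability (Pearson correlation of GEBVs with masked plant means)
  and a realized-gain mixed model whose cycle slope estimates genetic gain
  per selection cycle (Wald F test).
* **Data handling**: VCFtools `--012` dosage files, a minimal VCF reader,
  GBS-style QC filters (depth masking, missingness, MAF, parent-informed
  filters), mean imputation and the VanRaden relationship matrix
  `K = WW'/(2Σp(1−p))`.

The synthetic-data module (`squashgs.simpop`) simulates the whole study
design — biparental F2 populations under Haldane meiosis, multi-trait
additive architectures with exact h²/t/correlation targets, fruit-level
records with site structure, and depth-limited GBS genotype noise — so every
stage runs and is tested end to end without external data.

## Worked example

```python
import numpy as np
from squashgs import simpop, markers, mixedmodel, quantgen

# a 300-plant F2 with one trait at h2 = 0.25, t = 0.55, two field sites
gmap = simpop.GeneticMap.uniform(n_chrom=10, markers_per_chrom=30)
founders = simpop.make_founders(gmap.n_markers, gmap)
pop = simpop.make_f2_population(founders, 300, gmap, simpop.child_rng(1, 0))
arch = simpop.assign_architecture(gmap, [0.25], [0.55],
                                  rng=simpop.child_rng(1, 1),
                                  sites=("S1", "S2"), trait_names=["brix"])
records = simpop.simulate_records(pop, arch, simpop.child_rng(1, 2))

K = markers.vanraden_grm(pop.dosage_matrix().astype(float), ids=pop.ids)
fit = mixedmodel.repeatability_fit(records, "brix", K)
t, h2 = quantgen.repeatability_heritability(fit)
print(f"h2 = {h2:.3f}, t = {t:.3f}, PAmax = {quantgen.pa_max(h2):.3f}")
```

prints (seed 1)

```
h2 = 0.360, t = 0.614, PAmax = 0.600
```

The estimates recover the simulated truth (h² = 0.25, t = 0.55) up to the
sampling error of a single 300-plant population — averaged over seeds the
bias vanishes, which is what the test suite asserts at 800 plants × 20
seeds.  `PAmax` is the ceiling phenotypic mass selection could reach for
this trait; a genomic model's cross-validated predictive ability is judged
against it.

The same stack runs from the shell:

```bash
squashgs simulate --seed 1 --out run/          # population + phenotypes + 012 genotypes
squashgs qc   --geno run/geno --out run/geno_qc
squashgs grm  --geno run/geno_qc --out run/k.csv
squashgs fit  --model repeatability --pheno run/pheno.csv \
              --grm run/k.csv --traits brix --out run/fit
squashgs recurrent --seed 1 --out run/trajectory.csv   # full GS scheme
```

## Layout

```
src/squashgs/
  simpop.py      synthetic populations, architectures, records, GBS noise
  markers.py     genotype QC, merging, imputation, VanRaden GRM, 012/VCF I/O
  mixedmodel.py  EM-REML engine, repeatability + MT-GBLUP fits, BLUP, LRT, Wald F
  quantgen.py    t/h2/PAmax/Δr formulas, phenotypic & genetic correlations
  selection.py   Smith–Hazel and GEBV indices, culling, recurrent-GS driver
  evaluation.py  CV schemes, predictive ability, realized-gain model
  cli.py         squashgs command-line interface and test fixtures
docs/methods.md  model details, numerical choices, limitations
```
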