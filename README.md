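# ldhet

Genomic prediction and SNP-heritability estimation under regional linkage-
disequilibrium (LD) heterogeneity.

LD is not spread evenly along a genome: some regions carry long stretches of
strongly correlated SNPs, others are close to linkage equilibrium. In a
standard genomic relationship matrix (GRM) every SNP counts once, so causal
variants in high-LD regions are effectively counted many times and those in
low-LD regions barely at all. The result is a characteristic pathology of
GBLUP/GREML analyses on dense panels: genetic variance is overestimated for
high-LD regions, underestimated for low-LD regions, heritability estimates
are biased whenever causal variants cluster by LD level, and prediction
accuracy drops. `ldhet` implements the full workflow to quantify this effect
and the two standard corrections, for people working on genomic selection in
livestock (or any species with dense SNP data):

* **GCTA model** — single random genetic effect with the uniform-weight GRM
  `G = XX′/N`, where `X` holds dosages standardized as
  `x_ij = (m_ij − 2p_j)/√(2p_j(1−p_j))`.
* **LDAK model** — the LD-weighted GRM `G = XWX′/N`, `W = diag(w*_j)`, where
  the weights solve a non-negative least-squares system that drives each
  SNP's *replicate tagging* `Σ_k r²_jk·w_k` toward 1.
* **GREML-LDS** (`GCTA-LDS` / `LDAK-LDS`) — SNPs stratified into five equal
  groups by regional mean LD score, one GRM and one variance component per
  group: `y = 1μ + Σ_t g_t + e`, `g_t ~ N(0, G_t σ²_gt)`.

Variance components are estimated by constrained average-information REML,
predictions are GBLUP conditional means, and a synthetic-genotype module
generates panels with tunable, regionally coherent LD heterogeneity so the
whole pipeline is testable without any data download. PLINK 1 BED/BIM/FAM
and GCTA binary GRM files are read and written natively; EBV deregression
(`g_i/r_i²`) and 10×10-fold cross-validation support real-trait workflows.

## A worked example

```python
import numpy as np
import ldhet
from ldhet.experiment import ModelGRMs

panel = ldhet.simulate_genotypes(n_individuals=600, n_snps=4000,
                                 n_chromosomes=3, chrom_length=20_000_000,
                                 seed=11)
builder = ModelGRMs(panel)                      # LD profile + all model GRMs
tagging = ldhet.classify_tagging(panel, builder.profile.ld_score)

rng = np.random.default_rng(13)
causal = ldhet.select_causal(panel, tagging, "weak", 100, rng)   # low-LD causal
trait = ldhet.simulate_phenotypes(panel, causal, h2=0.8, seed=rng)

for model in ("GCTA", "GCTA-LDS"):
    fit = ldhet.reml_fit(trait.phenotype, builder.for_model(model))
    print(model, round(fit.h2_total, 3))
```

Output from this exact script (true h² = 0.8):

```
GCTA 0.709
GCTA-LDS 0.788
```

One replicate is noisy; averaged over 8 replicates
(`python examples/03_heritability_bias.py` prints this table) the contrast
is clear:

```
average-tagging causal variants (true h2 = 0.8, 8 replicates):
  single-GRM     mean h2 = 0.788 (sd 0.120)
  LD-stratified  mean h2 = 0.788 (sd 0.105)
weak-tagging causal variants (true h2 = 0.8, 8 replicates):
  single-GRM     mean h2 = 0.648 (sd 0.065)
  LD-stratified  mean h2 = 0.819 (sd 0.070)
```

Both models are unbiased when causal variants are spread genome-wide; when
the causal variants sit in weakly tagged, low-LD regions only the
five-component stratified model stays near the simulated value (at the
larger reference scale used by the acceptance script the single-GRM bias is
far more severe, ĥ² ≈ 0.4–0.6).

The `examples/` directory has one short script per capability: panel
simulation and PLINK output, LD profiling and LDAK weights, heritability
bias, GBLUP prediction of the four models, the replicated
ANOVA/paired-t comparison protocol, heritability enrichment per LD level
with the panel-density contrast, and EBV deregression with repeated
cross-validation.

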