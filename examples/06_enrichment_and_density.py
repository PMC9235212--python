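"""Heritability enrichment per LD level, and the panel-density contrast.

First partitions the genetic variance of a low-LD-causal trait across the
five LD levels (enrichment = variance share / SNP share). Then compares
genomic prediction between the full panel and an evenly thinned
medium-density panel, with causal variants removed from both.
"""

import numpy as np

import ldhet
from ldhet.experiment import ModelGRMs, density_comparison

panel = ldhet.simulate_genotypes(n_individuals=500, n_snps=3000, n_chromosomes=2,
                                 chrom_length=20_000_000, seed=29)
builder = ModelGRMs(panel)
profile = builder.profile
grms = builder.for_model("GCTA-LDS")
counts = np.array([g.n_snps for g in grms])

rng = np.random.default_rng(31)
low_ld = np.where(profile.ld_level >= 4)[0]   # causal confined to low-LD levels
causal = np.sort(rng.choice(low_ld, 100, replace=False))
trait = ldhet.simulate_phenotypes(panel, causal, h2=0.8, seed=rng)
fit = ldhet.reml_fit(trait.phenotype, grms)
enrich = ldhet.heritability_enrichment(fit, counts)
print("heritability enrichment per LD level (1 = very high LD ... 5 = very low):")
for level, e in enumerate(enrich, start=1):
    print(f"  level {level}: {e:.2f}")
print("  values > 1 mean the level explains more variance than its SNP share;")
print("  the causal variants were placed in levels 4-5, which should stand out.\n")

table = density_comparison(panel, medium_target=600, tagging_class="weak",
                           n_causal=80, n_replicates=5, master_seed=37)
wide = table.pivot(index="replicate", columns="density", values="accuracy")
print("single-GRM accuracy, weak-tagging trait, causal SNPs removed:")
print(f"  high density (m={panel.n_snps - 80}): mean {wide['high'].mean():.3f}")
print(f"  medium density (m~{600 - 80}):       mean {wide['medium'].mean():.3f}")
print("With causal variants in low-LD regions, the dense panel's extra high-LD")
print("SNPs dilute the signal, so the thinned, evenly spaced panel can predict")
print("as well or better - the density paradox that LD-aware models resolve.")
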