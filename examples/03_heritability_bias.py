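"""How LD heterogeneity biases SNP-heritability, and how stratification fixes it.

Simulates traits with true h² = 0.8 whose causal variants are either spread
genome-wide ("average" tagging) or confined to weakly tagged, low-LD regions,
then fits the single-GRM model and the five-component LD-stratified model.
"""

import numpy as np

import ldhet
from ldhet.experiment import ModelGRMs

panel = ldhet.simulate_genotypes(n_individuals=600, n_snps=4000, n_chromosomes=3,
                                 chrom_length=20_000_000, seed=11)
builder = ModelGRMs(panel)
tagging = ldhet.classify_tagging(panel, builder.profile.ld_score)
gcta = builder.for_model("GCTA")
lds = builder.for_model("GCTA-LDS")

for scenario in ("average", "weak"):
    ests = {"single-GRM": [], "LD-stratified": []}
    for rep in range(8):
        rng = np.random.default_rng([13, rep])
        causal = ldhet.select_causal(panel, tagging, scenario, 100, rng)
        trait = ldhet.simulate_phenotypes(panel, causal, h2=0.8, seed=rng)
        ests["single-GRM"].append(ldhet.reml_fit(trait.phenotype, gcta).h2_total)
        ests["LD-stratified"].append(ldhet.reml_fit(trait.phenotype, lds).h2_total)
    print(f"{scenario}-tagging causal variants (true h2 = 0.8, 8 replicates):")
    for model, vals in ests.items():
        print(f"  {model:14s} mean h2 = {np.mean(vals):.3f} (sd {np.std(vals):.3f})")
print("\nWith genome-wide causal variants both models are unbiased; when causal")
print("variants sit in low-LD regions the single-GRM estimate collapses while")
print("the five-component model, which gives each LD level its own variance,")
print("stays near the true value.")
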