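# Methods

`ldhet` studies how heterogeneity of linkage disequilibrium (LD) along the
genome affects genomic prediction (GBLUP) and SNP-heritability estimation
(GREML), and implements the two standard corrections: LD-weighted
relationship matrices (LDAK-style) and LD-stratified multi-component models
(GREML-LDS). This note documents the models, the synthetic-data generator,
the numerical choices, and the limitations of what the tests demonstrate.

## Mixed models

All analyses are variants of the linear mixed model

    y = 1μ + Σ_t g_t + e,   g_t ~ N(0, G_t σ²_t),   e ~ N(0, I σ²_e),

with one phenotype record per individual and an intercept as the only fixed
effect. Four specifications are compared:

| model    | components | GRM per component                        |
|----------|-----------:|------------------------------------------|
| GCTA     | 1          | G = XX′/N, uniform SNP weights            |
| LDAK     | 1          | G = XWX′/N, W = diag(w\*) LD weights      |
| GCTA-LDS | 5          | uniform GRM per LD level                  |
| LDAK-LDS | 5          | LD-weighted GRM per LD level              |

X holds standardized dosages x_ij = (m_ij − 2p_j)/√(2p_j(1−p_j)); this
standardization encodes the assumption that every causal variant contributes
equally to heritability, and the trait simulator is built to satisfy it
exactly. No covariances between component effects are modelled.

SNP-heritability is reported as the share of phenotypic variance:
h² = Σ_t d_t σ²_t / (Σ_t d_t σ²_t + σ²_e) with d_t = tr(G_t)/n. For
standard GRMs d_t ≈ 1, so this is the conventional ratio; the factor makes
the estimate exactly invariant to rescaling any relationship matrix.

## LD metrics

* **Pairwise LD** is the squared Pearson correlation r² of mean-imputed
  dosages.
* **SNP LD score**: Σ_k r²_jk over all SNPs within a 10-Mb window centered
  on SNP j (self pair included, so scores ≥ 1); windows never cross
  chromosomes. The bottom 20/40% and top 40/20% of scores define the very
  weakly / weakly / strongly / very strongly *tagged* SNP classes from which
  causal variants are drawn.
* **Regional mean LD score**: SNP scores averaged within 100-kb segments
  sliding by 50 kb from the first SNP of each chromosome; a SNP's regional
  score is the mean over all segments containing it. The 50-kb step (i.e.
  half-overlapping segments) halves boundary artifacts; both segment and
  step are configurable.
* **LD stratification**: SNPs sorted by regional score descending and cut
  into five contiguous, equal-size groups (remainders assigned from the
  high-LD end), giving LD levels 1 (very high) … 5 (very low).
* **LD (LDAK) weights**: per chromosome, w ≥ 0 minimizes
  Σ_j (1 − Σ_{k∈win(j)} r²_jk w_k)² with a 1-Mb window. Because r² outside
  the window does not enter, the system is banded and is solved in chunks of
  400 SNPs with full-window buffers (chunked and whole-chromosome solves
  agree to <5·10⁻³). A ridge of 1e-4 makes the minimizer unique when SNPs
  are perfectly correlated (the symmetric solution: duplicated SNPs share
  weight). Scaled weights w\* = w·N/Σw sum to the SNP count.
* **Replicate tagging**: Σ_{k∈win(j)} r²_jk·weight_k with a 1-Mb window —
  how often SNP j's signal is counted in a GRM. It is ≥ 1 unweighted and
  should average ≈ 1 after LD weighting; this is the diagnostic the weights
  are solved to satisfy.

The 1-Mb weight/tagging window (distinct from the 10-Mb score window) keeps
the quadratic programs local; it is exposed as a parameter.

## REML and prediction

Variance components are estimated by restricted maximum likelihood with an
intercept-only fixed effect: four EM burn-in iterations, then
average-information (AI) Newton steps until |ΔlogL| < 1e-6 (default) or 100
iterations. Components whose updates go negative are pinned at 1e-8·var(y);
pinned components with an inward-pointing score are excluded from the AI
system (constrained AI-REML). An AI step that would decrease the restricted
likelihood is step-halved up to four times and then replaced by an EM step,
so the likelihood is non-decreasing after burn-in. Correctness is anchored
by a brute-force grid search over the restricted-likelihood surface on
small fixtures.

AIC = −2·logL_R + 2k with k = number of variance components (T + 1); fixed
effects are excluded because the restricted likelihood already conditions
on them. Only AIC differences between models on the same data are used.

GBLUP predictions for validation individuals are the conditional means
GEBV = C_vt V_tt⁻¹ (y_train − μ̂), with μ̂ the GLS intercept on the training
data; this equals the solution of the explicit mixed-model equations
(verified against a dense MME solve in the tests). Variance components are
re-estimated within each training fold — never on data that includes the
validation individuals. Prediction accuracy is the Pearson correlation
between GEBV and the reference (true genetic values in simulations,
deregressed EBV for real traits).

Per-group heritability enrichment is (σ²_t/Σσ²_u)/(m_t/m_total): 1 means a
group explains variance in proportion to its SNP count.

## Synthetic genotypes

The generator produces diploid dosages with *regionally coherent* LD, the
condition under study, without a demographic model:

* Each chromosome is tiled with **LD regions** (1–5 Mb) whose base
  correlation is drawn uniformly from the configured range (default
  0.3–0.99), emulating genomes in which Mb-scale regions have consistently
  high or low LD.
* Regions are tiled with **haplotype blocks** (10–500 kb). A block's
  adjacent-SNP haplotype correlation ρ is the region base ±0.05 (clipped);
  all SNPs in a block share one allele frequency drawn from the MAF range
  (default 0.01–0.5). With equal within-block frequencies the two-state
  Markov transition probabilities are exact for any ρ, and the adjacent-SNP
  dosage r² is ρ².
* Haplotypes follow the block Markov chain (correlation 0 across block
  boundaries); two independent haplotypes are summed per individual. SNP
  positions are uniform random, then sorted.

At the reference scale (n=1000, m=10000, 3×25 Mb) the 90th/10th percentile
ratio of regional mean LD scores is ≈ 5–7, comfortably past the ≥3
"severalfold heterogeneity" bar asserted in the tests.

Traits: m causal SNPs (default 100) drawn uniformly from a tagging class
receive |a_i| = (2p_i(1−p_i))^(−1/2)·δ_g/√m, δ_g = √(δ_p²·h²), so each
contributes exactly δ_g²/m of genetic variance; environmental noise is
N(0, (1−h²)δ_p²) and y = Xa + e with δ_p² = 1. Effect *signs* are
randomized by default (a flag restores all-positive effects): variance
contributions are sign-invariant, and with all-positive effects correlated
causal pairs would inflate var(tbv) above δ_g².

What the generator does **not** emulate: cattle demography and pedigree
structure, selection, the MAF–LD coupling of the real bovine genome, or
genetic maps (all windows are in bp). Passing tests therefore demonstrate
the *mechanisms* — tagging-dependent bias and its correction — not the
numeric accuracy/heritability values of any real cattle trait.

## Experiment protocol

Per replicate: a fresh trait on the shared panel, a random 90/10
train/validation split, REML on training, GBLUP to validation. Replicate
seeds derive from (master seed, scenario index, replicate index), so
replicates are paired across models and the grid is bit-reproducible.
Genotypes are simulated once and reused across replicates (a flag enables
fresh panels), mirroring studies that reuse one real genotype set.

Model comparison: one-way ANOVA across models per metric, gated at 0.05;
if significant, all pairwise paired t-tests with Bonferroni adjustment
(×C(models,2)) and `*`/`**`/`***` codes at 0.05/0.01/0.001. Pairs with zero
within-pair variance and a nonzero shift are flagged degenerate and
reported with p = 0.

The density experiment builds a medium panel from evenly spaced SNPs
(per-chromosome allocation proportional to SNP counts), removes the causal
variants from both panels, and evaluates the same traits under both,
paired by replicate. Removing k causal columns from a precomputed GRM is a
rank-k downdate, so per-replicate GRMs are cheap.

Deregression of EBV: standardize to mean 0, variance 1 (population
variance), then divide by the reliability r²; heterogeneous reliabilities
inflate the variance above 1, which is expected.

## Numerical choices and degenerate inputs

* Missing dosages are mean-imputed (2p_j) after QC for all LD/GRM work;
  imputed entries standardize to exactly 0.
* Allele frequencies for standardization are computed once on the full
  analysis sample per panel; the GRM covers train ∪ validation before any
  split.
* HWE is tested with the 1-df Pearson chi-square on genotype counts (the
  conventional chip-QC choice), default p-cutoff 1e-6; monomorphic SNPs are
  removed unconditionally.
* Tagging-class ties break by (score, chromosome, position); LD-level
  remainders go to the high-LD end — both purely for determinism.
* LDAK weights within an LD level are re-scaled so Σw\* = N_t per level,
  keeping the five component GRMs on a common scale (flag-controlled).
* Within windows no r² thresholding or truncation is applied.
* Zero-variance SNPs raise immediately (run QC first); an all-SNP-removing
  QC raises an explicit empty-panel error; REML non-convergence is flagged
  on the result, not raised.

## Problem sizes

The acceptance script runs the reference conditions: n=1000, m=10000,
3×25 Mb, 30 replicates per scenario, 100 causal SNPs, h² ∈ {0.8, 0.5}
(≈10–15 min on one CPU). The pytest suite exercises the same pipelines at
reduced sizes chosen for statistical power per minute — panels of 150–1000
individuals and 600–5000 SNPs, 12–20 replicates — so the full suite stays
within a coffee break. Reduced scale lowers the regional-heterogeneity
ratio (the null-r² noise floor ≈ window-SNP-count/n compresses score
quantiles), which the affected tests account for by using panels large
enough for the property under test.

## Known limitations

* Dense-matrix algebra throughout: n is comfortably a few thousand, not
  hundreds of thousands.
* LD weights are solved per chromosome with a local window; agreement with
  the LDAK software's exact weights is approximate by construction (the
  original defers to its own solver), and the MAF-dependent power parameter
  ("alpha") of later LDAK versions is out of scope.
* bp windows only; no genetic-map (cM) support.
* Single-record phenotypes with an intercept; no additional fixed effects
  or repeated measures.
* Autosomes only; sex chromosomes are not modelled.
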