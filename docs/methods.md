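# Methods

## Study design and models

The package targets paired designs: each individual contributes a tumor and
an adjacent-normal expression sample, genotypes are germline (shared by both
samples), and expression is analysed as log2(TPM + 1).  Status is coded
tumor = 1, normal = 0.

**Variant QC.**  Variants are kept when minor allele frequency ≥ 0.01,
missing call rate ≤ 0.05, exact Hardy–Weinberg p ≥ 1e-6, the minor allele is
carried by ≥ 10 individuals, and the variant is not on chrY; all filters are
applied jointly and each variant's failure reasons are reported.  The HWE
test is the exact conditional test: given the allele counts, the probability
of heterozygote count *h* is `multinomial(n; n_AA, h, n_aa)·2^h / C(2n, n_minor)`,
and the two-sided p sums the probabilities of all *h* whose probability does
not exceed the observed one.  Weights are exact integers (Python big ints)
and the final p is an exact rational converted to float, so tie handling in
the "≤ observed" rule carries no floating-point ambiguity and the test
agrees with a full-enumeration oracle to 1e-12 for every table with ≤ 400
alleles.  Missing genotypes are retained through QC (they count toward
missingness) and handled complete-case within each downstream model fit; no
imputation is performed.

**Cell fractions.**  Downstream models use only the epithelial fraction.
Fractions may be supplied precomputed (e.g. from an external deconvolution
service) or estimated by the built-in reference-based estimator: per bulk
sample, non-negative least squares of the TPM profile on the
epithelial/immune/stromal signature columns over shared genes (≥ 10
required), with coefficients renormalised to sum to one.  A sample whose
NNLS solution is identically zero receives uniform fractions with a warning.

**Stage 1 — fraction-interaction scan.**  Cis pairs are all (variant, gene)
combinations on one chromosome with |variant pos − TSS| ≤ 1 Mb (the standard
cis convention; configurable).  tss_distance is signed and strand-aware
(variant − TSS, flipped for − strand genes).  Within one status the model
per pair is OLS of y on `[1, covs, G, f, G·f]` with the two-sided *t*-test
on G·f.  Covariates are the binary clinical variables (age group, sex,
smoking, drinking), genotype PCs (2 for tumor, 3 for normal by default;
computed from mean-imputed dosages scaled by `sqrt(2p(1−p))`, deterministic
sign convention), and any supplied hidden expression factors.  Rank-deficient
designs (e.g. constant fraction) yield NA-flagged results rather than being
dropped.

**Hierarchical correction.**  Gene-level p = Simes combination of the gene's
SNP p-values; BH across genes at α = 0.01 selects R of G genes; SNP-level BH
within selected genes at level (R/G)·α.  The stored `p_adjusted` is the
within-gene BH value scaled by G/R, so `significant ⇔ p_adjusted ≤ α`.  This
two-level Simes+BH concretisation is a declared design choice; alternatives
exist, and the implementation is oracle-tested against an independent naive
reimplementation.  Per gene, the most significant eQTL (ties: smaller
|tss_distance|, then variant id) is carried to stage 2, reducing
LD-driven redundancy.

**Stage 2 — paired mixed model.**  For each top pair the full model is

    y = β0 + βg·G + βs·s + βgs·G·s + Σ_k (γk·ck + δk·s·ck) + u_ind + ε

with u ~ N(0, σu²) per individual and ε ~ N(0, σe²).  Both the full and the
no-interaction model are fitted by ML (not REML, since the comparison
involves fixed effects) and the primary test is the 1-df LRT; the Wald test
on βgs is reported alongside.  Unpaired individuals are dropped (logged).
Because each kept individual has exactly one observation per status, the
orthonormal rotation m = (y_T + y_N)/√2, d = (y_T − y_N)/√2 decorrelates the
random intercept: Var(m) = σe² + 2σu², Var(d) = σe², independent.  ML
therefore reduces to a one-dimensional concentrated likelihood in
r = Var(d)/Var(m) ∈ (0, 1], minimised by bounded Brent on log r (tolerance
1e-10) with the σu = 0 boundary (r = 1) checked explicitly; fixed effects
come from the GLS normal equations at the optimum.  The fitter is validated
against statsmodels MixedLM (ML) to ~1e-5 in a unit test; its speed
(< 1 ms per fit at n = 120 pairs) is what makes the permutation null
affordable.

**Permutation null.**  Under the no-interaction null, the tumor/normal
labels within an individual are exchangeable.  Each of B permutations swaps
the labels within each individual independently with probability 1/2;
observations keep their expression values and observation-level covariates
(the epithelial fraction), while the status column and all status×covariate
columns are rebuilt.  p_empirical = (1 + #{T_b ≥ T_obs})/(1 + B), so its
range is [1/(B+1), 1].  B ≥ 100 is enforced; the pipeline default is 1,000
(the bundled end-to-end runs use 200).

**Gain/loss classification.**  The category names describe where the eQTL
acts; the decision rule binds them to scan-context membership gated by the
interaction test: among pairs with p_empirical < 0.05, a pair significant in
the tumor scan only is *gain*, in the normal scan only is *loss*, in both is
*shared*; everything else is *ns*.  A sign-of-βgs rule is a reasonable
alternative and the classifier is written so it can be substituted; the
membership rule is the default because the top-eQTL lists are exactly the
objects the two scans produce.

**Colocalization / fine-mapping.**  Wakefield log-ABF
`½[log(1−r) + r·z²]`, r = W/(V+W), with prior effect variance W = 0.15² for
quantitative and 0.2² for binary traits; priors p1 = p2 = 1e-4, p12 = 1e-5
(the conventional defaults; configurable).  The five-hypothesis posterior is
computed entirely in log space (logsumexp; the H3 term uses a log-space
difference), so ABFs up to exp(700) cannot overflow.  Summary statistics
without betas are converted via z = Φ⁻¹(1 − p/2) and
se = 1/√(2·maf·(1−maf)·N) (scaled by case fraction for binary traits); the
missing sign is irrelevant since the ABF depends on z².  Fine-mapping
assumes a single causal variant with a uniform prior: PIP = softmax(log ABF),
and the 99% credible set is the smallest PIP-descending prefix reaching
0.99 (PIP ties broken by variant id).

**Markers and survival.**  Differential expression: paired Wilcoxon
signed-rank on log2(TPM+1) (≥ 6 complete pairs), BH across genes, calls
gated by fold change of mean TPM (> 1.2 up, < 0.8 down) at q < 0.05.
Promoter enrichment: 2×2 Fisher exact test of gain vs loss eQTLs within
± 2 kb of the TSS (window configurable and reported), odds ratio with
Haldane 0.5 correction on zero cells.  Survival: dominant (carrier)
genotype grouping — dosage 0 vs {1, 2} — with the two-group log-rank test
and a Cox model (Efron ties, via lifelines) adjusted for age group, sex,
smoking, drinking and TNM stage; Wald 95% CIs; non-convergence and complete
separation are NA-flagged.

## Synthetic cohort

The generator emulates the paired design directly on the log2(TPM+1) scale
and back-transforms through TPM = max(2^y − 1, 0), so the downstream log
transform recovers the generative scale exactly; the generative family is
exactly the family the two stages fit, so estimator bias is directly
measurable.  Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| individuals / variants / genes | 120 / 200 / 50 | desk-scale paired cohort |
| MAF | Uniform(0.05, 0.5) | common variants, HWE by construction |
| epithelial fraction, tumor | Beta(2.4, 1.6) (mean 0.60, SD ≈ 0.22) | wide purity spread typical of bulk tumors |
| epithelial fraction, normal | Beta(2, 3) (mean 0.40, SD = 0.20) | lower, status-distinct mean |
| noise SD / random-intercept SD | 1.0 / 0.5 (log2 units) | moderate within/between-individual variance |
| planted β_gxf | 5.0 per allele per unit fraction | see power note below |
| planted β_gxs magnitude | 1.0 per allele | detectable by the paired LRT at n = 120 |
| label proportions | 70% null, 10% each shared/gain/loss | sparse signal |

Label semantics: *gain* effects (G·f interaction and the G·s term) are
expressed in tumor samples only; *loss* effects in normal samples only
(β_main = b with β_gxs = −b, so the normal-side effect is larger); *shared*
effects in both with no status interaction; *null* pairs have all betas
zero.  One designated causal pair per gene (the lattice variant nearest the
TSS); label counts follow the proportions exactly under largest-remainder
rounding, with a seeded permutation deciding which gene gets which label.
Genes sit every 100 kb on one synthetic chromosome (alternating strand, TSS
strand-resolved); variants sit on a 5-kb lattice spanning the gene region so
every gene has cis variants.

*Power note.*  The standard error of the G·f interaction estimate is
approximately `σ/(√n·sd(G)·sd(f))` ≈ 0.64 at n = 120, MAF 0.3 and fraction
SD 0.2, so a recovery experiment that expects ≥ 90% of planted pairs to
clear the hierarchical threshold needs |β_gxf|/0.64 well above the ≈ 3.9
critical *t*.  The default of 5.0 puts per-pair detection power above 99%,
so classification failures reflect pipeline defects rather than sampling
noise.  Bias studies use β_gxf = 0.8, where the estimate is noisy but
median-unbiased.

**What the generator does not emulate:** LD between variants (cis variants
are independent; only the colocalization/fine-mapping simulator has an LD
block), population structure, indels, count-level sampling noise
(expression noise is Gaussian on the log scale), trans effects, and hidden
batch structure (hidden factors are accepted as covariates but not
generated).  Passing recovery tests therefore demonstrates correctness of
the estimators and decision rules under the declared model, not robustness
to LD-driven confounding or non-Gaussian expression noise in real cohorts.

## Numerical choices and degenerate inputs

- All positions are 1-based (VCF convention); chromosome names are
  normalised to the "chr" dialect; the annotation must supply strand-resolved
  TSS values directly.
- Multi-allelic VCF records are skipped with a logged count; "./." and
  half-calls are missing; duplicate variant or gene ids are hard errors.
- The LRT statistic is clipped at 0 before the χ² tail (the optimizer can
  leave ~1e-9 negative residue); permutation counting uses a 1e-9 tolerance
  on T_b ≥ T_obs so exact symmetries count as ties.
- Monomorphic variants contribute nothing to genotype PCA (scale guard);
  constant covariate columns are dropped with a warning.
- An all-zero NNLS solution falls back to uniform fractions with a warning;
  an all-zero raw fraction row is an error naming the sample.
- Empty candidate structures (no cis pairs, genes with no significant pair)
  are valid empty results, not errors; empty input matrices are errors.

## Validation scale

The bundled validation studies (test suite and `scripts/acceptance.py`) use:
the full HWE enumeration up to 400 alleles; 1,000-variant QC cohorts; 2,000
null scan tests; 200-gene recovery panels; 200–400 permutation-null genes at
B = 150–200; a 125-gene cohort with 50 gain + 50 loss planted pairs; 200
colocalization and 500 fine-mapping replicates; and 200 Cox coverage
replicates — sizes chosen so the whole suite runs in minutes on one CPU
while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

- Single random intercept only; no status-heteroscedastic residuals, no
  multi-level random effects.
- Single-causal fine-mapping; no LD-aware conditional analysis or
  multi-signal (SuSiE-style) models.
- The hierarchical correction and the gain/loss rule are declared
  concretisations of procedures that admit variants; both are isolated
  behind single functions and oracle-tested.
- trans-eQTLs, PEER factor inference, and external deconvolution services
  are out of scope; their outputs are consumed as inputs where relevant.
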