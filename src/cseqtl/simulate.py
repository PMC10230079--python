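"""Synthetic paired tumor/normal cohort with planted eQTL effects.

The generator emulates the study design downstream stages expect: ~120
individuals, each contributing one tumor and one normal expression sample;
epithelial cell fractions whose distribution differs by disease status;
binary clinical covariates; and planted genotype effects of three kinds —
a main effect, a genotype x epithelial-fraction interaction, and a
genotype x status interaction.

Expression is generated on the log2(TPM + 1) scale,

    y = mu_g + sum_k gamma_k cov_k + delta_g f + beta_main G
        + beta_gxf G f [in the label's status context]
        + beta_gxs G s + u_individual + eps,

with u ~ N(0, sd_random_intercept^2) shared by an individual's two samples
and eps ~ N(0, sd_noise^2), then back-transformed to TPM = max(2^y - 1, 0)
so that the downstream log2(TPM + 1) transform recovers y exactly where
TPM > 0.  The generative family is exactly the model family fitted in the
scan and mixed-model stages, so estimator bias is directly measurable.

Planted-label semantics (matching the gain/loss definitions downstream):

* ``null``    — all betas zero.
* ``shared``  — main effect and G x fraction effect in both statuses;
  no G x status interaction.
* ``gain``    — effects expressed only in tumor samples: beta_gxs > 0,
  G x fraction applied to tumor samples only, no main effect.
* ``loss``    — effects expressed only in normal samples: beta_main > 0
  with beta_gxs = -beta_main, G x fraction applied to normal samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CellFractionTable,
    ConfigError,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    SampleSheet,
    ValidationError,
    VariantRecord,
)

LABELS = ("null", "shared", "gain", "loss")

_GENE_SPACING = 100_000  # bp between consecutive TSSs on the synthetic chromosome
_VARIANT_LATTICE = 5_000  # variants sit on a 5-kb lattice
_CHROM = "chr1"
_FIRST_TSS = 500_000


@dataclass
class SimConfig:
    """Cohort shape, noise levels and planted effect sizes.

    Defaults are desk scale: 120 individuals (two samples each), 200
    variants and 50 genes on one synthetic chromosome.  Epithelial-fraction
    Beta parameters give a wide purity spread (tumor mean 0.6, normal mean
    0.4, SD ~0.2 each), typical of bulk tumor cohorts and necessary for the
    genotype x fraction term to be identifiable at this sample size.
    """

    n_individuals: int = 120
    n_variants: int = 200
    n_genes: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    # epithelial-fraction Beta(a, b) per status (0 = normal, 1 = tumor)
    fraction_beta: dict = field(
        default_factory=lambda: {0: (2.0, 3.0), 1: (2.4, 1.6)})
    sd_random_intercept: float = 0.5
    sd_noise: float = 1.0
    n_covariates: int = 4
    covariate_effect_sd: float = 0.5
    fraction_effect_sd: float = 1.0
    baseline_mean: float = 4.0
    baseline_sd: float = 1.0
    # planted effect sizes (log2 expression units per alt allele)
    beta_gxf: float = 5.0   # per unit epithelial fraction
    beta_gxs: float = 1.0   # tumor-vs-normal interaction magnitude
    beta_main: float = 1.0  # main effect for "shared" pairs
    label_proportions: dict = field(
        default_factory=lambda: {"null": 0.7, "shared": 0.1,
                                 "gain": 0.1, "loss": 0.1})
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 20:
            raise ConfigError("n_individuals must be >= 20")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        for s, (a, b) in self.fraction_beta.items():
            if a <= 0 or b <= 0:
                raise ConfigError(f"Beta parameters for status {s} must be positive")
        tot = sum(self.label_proportions.get(k, 0.0) for k in LABELS)
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError("label_proportions must sum to 1")
        if set(self.label_proportions) - set(LABELS):
            raise ConfigError(f"labels must be among {LABELS}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class SimTruth:
    """Planted effects per (variant, gene) pair, for recovery scoring."""

    table: pd.DataFrame  # variant_id, gene_id, label, beta_main, beta_gxf, beta_gxs

    def __post_init__(self):
        need = {"variant_id", "gene_id", "label",
                "beta_main", "beta_gxf", "beta_gxs"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"truth table missing {need - set(self.table.columns)}")
        bad = ~self.table["label"].isin(LABELS)
        if bad.any():
            raise ValidationError(f"unknown label {self.table.loc[bad, 'label'].iloc[0]}")
        t = self.table
        g = t[t.label == "gain"]
        if not ((g.beta_gxs > 0) & (g.beta_main == 0)).all():
            raise ValidationError("gain pairs must have beta_gxs > 0, beta_main = 0")
        l = t[t.label == "loss"]
        if not ((l.beta_gxs < 0) & (l.beta_main > 0)
                & np.isclose(l.beta_main + l.beta_gxs, 0)).all():
            raise ValidationError("loss pairs must have the normal-side effect larger")
        z = t[t.label == "null"]
        if not ((z[["beta_main", "beta_gxf", "beta_gxs"]] == 0).all().all()):
            raise ValidationError("null pairs must have all betas zero")

    def labels(self) -> pd.Series:
        return self.table.set_index(["variant_id", "gene_id"])["label"]


def simulate_gene_annotation(cfg: SimConfig) -> list[GeneAnnotation]:
    """Genes every 100 kb on one synthetic chromosome, alternating strand.

    For "-" strand genes the TSS is the larger coordinate of the span,
    matching the convention the annotation reader expects.
    """
    genes = []
    biotypes = ("protein_coding", "protein_coding", "lncRNA", "pseudogene")
    for g in range(cfg.n_genes):
        tss = _FIRST_TSS + g * _GENE_SPACING
        if g % 2 == 0:
            genes.append(GeneAnnotation(f"G{g:04d}", _CHROM, tss, tss + 20_000,
                                        "+", biotypes[g % 4]))
        else:
            genes.append(GeneAnnotation(f"G{g:04d}", _CHROM, tss, tss - 20_000,
                                        "-", biotypes[g % 4]))
    return genes


def _variant_positions(cfg: SimConfig) -> np.ndarray:
    """Variants on a 5-kb lattice spanning the gene region, so that every
    gene has cis variants."""
    span = cfg.n_genes * _GENE_SPACING
    step = max(_VARIANT_LATTICE,
               int(round(span / cfg.n_variants / _VARIANT_LATTICE)) * _VARIANT_LATTICE)
    return _FIRST_TSS - _GENE_SPACING // 2 + step * np.arange(cfg.n_variants)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Independent biallelic variants in Hardy-Weinberg proportions: per
    variant, MAF ~ Uniform(maf_range) and dosage ~ Binomial(2, MAF)."""
    rng = cfg.rng(1)
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=cfg.n_variants)
    dosages = rng.binomial(2, mafs[None, :],
                           size=(cfg.n_individuals, cfg.n_variants)).astype(float)
    positions = _variant_positions(cfg)
    variants = [VariantRecord(f"v{j:05d}", _CHROM, int(positions[j]), "A", "G")
                for j in range(cfg.n_variants)]
    individuals = [f"I{i:04d}" for i in range(cfg.n_individuals)]
    return GenotypeMatrix(individuals, variants, dosages)


def simulate_sample_sheet(cfg: SimConfig) -> SampleSheet:
    """One tumor + one normal sample per individual, binary clinical
    covariates, and censored survival follow-up (no planted genotype effect)."""
    rng = cfg.rng(2)
    rows = []
    for i in range(cfg.n_individuals):
        ind = f"I{i:04d}"
        age, sex, smoke, drink = rng.integers(0, 2, size=4)
        tnm = int(rng.integers(1, 5))
        t_event = rng.exponential(1500.0)
        t_cens = rng.uniform(200.0, 2500.0)
        surv_time = min(t_event, t_cens)
        surv_event = int(t_event <= t_cens)
        for status, tag in ((1, "T"), (0, "N")):
            rows.append(dict(sample_id=f"{ind}_{tag}", individual_id=ind,
                             status=status, age_group=int(age), sex=int(sex),
                             smoking=int(smoke), drinking=int(drink),
                             tnm_stage=tnm, surv_time=round(surv_time, 1),
                             surv_event=surv_event))
    return SampleSheet(pd.DataFrame(rows))


def simulate_fractions(cfg: SimConfig, sheet: SampleSheet) -> CellFractionTable:
    """Epithelial fraction ~ Beta(a_s, b_s) by status; the remaining mass is
    split between immune and stromal.  Rows sum to one by construction."""
    rng = cfg.rng(3)
    t = sheet.table
    epi = np.empty(len(t))
    for status, (a, b) in cfg.fraction_beta.items():
        mask = (t["status"] == status).to_numpy()
        epi[mask] = rng.beta(a, b, size=int(mask.sum()))
    w = rng.beta(2.0, 2.0, size=len(t))  # immune share of the non-epithelial mass
    imm = (1.0 - epi) * w
    stro = 1.0 - epi - imm
    fracs = np.column_stack([epi, imm, stro])
    return CellFractionTable(list(t["sample_id"]),
                             ["epithelial", "immune", "stromal"], fracs)


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to labels (deterministic)."""
    quotas = {k: n * proportions.get(k, 0.0) for k in LABELS}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    # break remainder ties in fixed label order
    by_rem = sorted(LABELS, key=lambda k: (-(quotas[k] - counts[k]), LABELS.index(k)))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def make_truth_table(cfg: SimConfig, pairs: list[tuple[str, str]] | None = None,
                     ) -> SimTruth:
    """Assign planted labels to candidate (variant_id, gene_id) pairs.

    ``pairs`` defaults to one designated pair per gene: the lattice variant
    nearest the gene's TSS.  Label counts follow ``label_proportions``
    exactly under largest-remainder rounding; which pair receives which
    label is a seeded permutation.
    """
    if pairs is None:
        genes = simulate_gene_annotation(cfg)
        positions = _variant_positions(cfg)
        pairs = []
        for g in genes:
            j = int(np.argmin(np.abs(positions - g.tss)))
            pairs.append((f"v{j:05d}", g.gene_id))
    n = len(pairs)
    if n == 0:
        raise ConfigError("no candidate pairs to label")
    counts = _allocate_counts(n, cfg.label_proportions)
    labels = [lab for lab in LABELS for _ in range(counts[lab])]
    rng = cfg.rng(4)
    perm = rng.permutation(n)
    rows = []
    for k, idx in enumerate(perm):
        v, g = pairs[idx]
        lab = labels[k]
        if lab == "null":
            bm, bf, bs = 0.0, 0.0, 0.0
        elif lab == "shared":
            bm, bf, bs = cfg.beta_main, cfg.beta_gxf, 0.0
        elif lab == "gain":
            bm, bf, bs = 0.0, cfg.beta_gxf, abs(cfg.beta_gxs)
        else:  # loss
            bm, bf, bs = abs(cfg.beta_gxs), cfg.beta_gxf, -abs(cfg.beta_gxs)
        rows.append(dict(variant_id=v, gene_id=g, label=lab,
                         beta_main=bm, beta_gxf=bf, beta_gxs=bs))
    table = pd.DataFrame(rows).sort_values(["gene_id", "variant_id"],
                                           kind="stable").reset_index(drop=True)
    return SimTruth(table)


def simulate_expression(geno: GenotypeMatrix, fractions: CellFractionTable,
                        sheet: SampleSheet, truth: SimTruth,
                        cfg: SimConfig,
                        gene_ids: list[str] | None = None) -> ExpressionMatrix:
    """Generate the TPM matrix from the planted generative model."""
    t = sheet.table
    samples = list(t["sample_id"])
    if set(fractions.sample_ids) != set(samples):
        raise ValidationError("fraction table samples do not match sample sheet")
    if gene_ids is None:
        gene_ids = sorted(truth.table["gene_id"].unique())
    rng = cfg.rng(5)

    n_s = len(samples)
    n_g = len(gene_ids)
    epi = fractions.column("epithelial").reindex(samples).to_numpy()
    status = t["status"].to_numpy(dtype=float)
    cov_cols = ["age_group", "sex", "smoking", "drinking"][: cfg.n_covariates]
    C = t[cov_cols].to_numpy(dtype=float) if cov_cols else np.zeros((n_s, 0))

    ind_ids = t["individual_id"].to_numpy()
    uniq_ind, ind_idx = np.unique(ind_ids, return_inverse=True)
    gidx = {ind: i for i, ind in enumerate(geno.individuals)}
    missing = [i for i in uniq_ind if i not in gidx]
    if missing:
        raise ValidationError(f"individuals without genotypes: {missing[:3]}")
    vidx = geno.variant_index()

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_g)
    gamma = rng.normal(0.0, cfg.covariate_effect_sd, size=(n_g, C.shape[1]))
    delta = rng.normal(0.0, cfg.fraction_effect_sd, size=n_g)
    u = rng.normal(0.0, cfg.sd_random_intercept, size=(n_g, len(uniq_ind)))
    eps = rng.normal(0.0, cfg.sd_noise, size=(n_g, n_s))

    y = (mu[:, None] + gamma @ C.T + delta[:, None] * epi[None, :]
         + u[:, ind_idx] + eps)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for row in truth.table.itertuples(index=False):
        if row.label == "null" or row.gene_id not in gene_pos:
            continue
        gi = gene_pos[row.gene_id]
        G = geno.dosages[[gidx[i] for i in ind_ids], vidx[row.variant_id]]
        G = np.nan_to_num(G)
        if row.label == "gain":
            ctx = status  # fraction interaction active in tumor samples only
        elif row.label == "loss":
            ctx = 1.0 - status
        else:
            ctx = np.ones(n_s)
        y[gi] += (row.beta_main * G + row.beta_gxf * G * epi * ctx
                  + row.beta_gxs * G * status)

    tpm = np.clip(np.exp2(y) - 1.0, 0.0, None)
    return ExpressionMatrix(list(gene_ids), samples, tpm)


@dataclass
class Cohort:
    cfg: SimConfig
    genotypes: GenotypeMatrix
    genes: list[GeneAnnotation]
    sheet: SampleSheet
    fractions: CellFractionTable
    truth: SimTruth
    expression: ExpressionMatrix


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate the full synthetic cohort used by the end-to-end pipeline."""
    geno = simulate_genotypes(cfg)
    genes = simulate_gene_annotation(cfg)
    sheet = simulate_sample_sheet(cfg)
    fractions = simulate_fractions(cfg, sheet)
    truth = make_truth_table(cfg)
    expr = simulate_expression(geno, fractions, sheet, truth, cfg,
                               gene_ids=[g.gene_id for g in genes])
    return Cohort(cfg, geno, genes, sheet, fractions, truth, expr)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write the cohort in the on-disk formats the readers consume."""
    import os

    from . import io as cio

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "expression": os.path.join(out_dir, "expression_tpm.tsv"),
        "annotation": os.path.join(out_dir, "genes.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "fractions": os.path.join(out_dir, "fractions.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    cio.write_vcf(cohort.genotypes, paths["vcf"])
    cio.write_expression(cohort.expression, paths["expression"])
    cio.write_annotation(cohort.genes, paths["annotation"])
    cio.write_sample_sheet(cohort.sheet, paths["samples"])
    cio.write_fractions(cohort.fractions, paths["fractions"])
    cohort.truth.table.to_csv(paths["truth"], sep="\t", index=False)
    return paths
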