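"""Stage 1: cis-pair enumeration, genotype PCs, the per-pair
genotype x epithelial-fraction interaction regression within one disease
status, and hierarchical multiple-testing correction.

Per cis pair the model is an ordinary least-squares fit of log2(TPM + 1) on
[intercept, covariates, G, f, G*f] where f is the epithelial fraction; the
reported test is the two-sided t-test on the G*f coefficient.  Pairs whose
design is rank-deficient (e.g. a constant fraction making G*f collinear
with G) are flagged NA rather than dropped.

The hierarchical correction is the two-level Simes + Benjamini-Hochberg
procedure: each gene's SNP p-values are Simes-combined into one gene-level
p; genes are BH-corrected at the target level; within the R of G genes that
pass, SNP-level BH is applied at level (R/G) * alpha.  ``p_adjusted`` is
stored on a scale directly comparable to alpha (within-gene BH value times
G/R), so significance is simply p_adjusted <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CellFractionTable,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    SampleSheet,
    ValidationError,
    VariantRecord,
    logger,
)

CLINICAL_COVARIATES = ("age_group", "sex", "smoking", "drinking")


@dataclass(frozen=True)
class CisPair:
    variant_id: str
    gene_id: str
    tss_distance: int  # signed bp: variant pos - TSS, sign flipped on "-" strand


@dataclass
class InteractionScanResult:
    pair: CisPair
    status_context: str  # "tumor" or "normal"
    beta_g: float = np.nan
    beta_f: float = np.nan
    beta_gxf: float = np.nan
    se_gxf: float = np.nan
    t_gxf: float = np.nan
    p_nominal: float = np.nan
    p_adjusted: float = np.nan
    significant: bool = False
    na_reason: str = ""


def enumerate_cis_pairs(variants: list[VariantRecord],
                        genes: list[GeneAnnotation],
                        window: int) -> list[CisPair]:
    """All (variant, gene) pairs on the same chromosome with
    |variant pos - TSS| <= window; tss_distance is strand-aware."""
    if window <= 0:
        raise ValueError("cis window must be positive")
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    pairs = []
    for g in genes:
        for v in by_chrom.get(g.chrom, ()):
            d = v.pos - g.tss
            if abs(d) <= window:
                pairs.append(CisPair(v.id, g.gene_id,
                                     -d if g.strand == "-" else d))
    return pairs


def genotype_pcs(geno: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k genotype principal components (columns PC1..PCk, one row per
    individual).

    Dosages are mean-imputed per variant, centred, and scaled by
    sqrt(2 p (1 - p)); monomorphic variants (p(1-p) = 0) are skipped.  Sign
    convention: the largest-magnitude entry of each component is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= geno.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    D = geno.dosages.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(D, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(D))
    D[idx] = col_mean[idx[1]]
    p = col_mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    Z = (D[:, ok] - col_mean[ok]) / scale[ok]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    U = U[:, :k]
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return pd.DataFrame(U, index=geno.individuals,
                        columns=[f"PC{j + 1}" for j in range(k)])


def build_covariates(sheet: SampleSheet, sample_ids: list[str],
                     pcs: pd.DataFrame | None = None,
                     hidden: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the named covariate matrix for the given samples: clinical
    binaries plus optional genotype PCs (per individual) and hidden
    expression factors (per sample, e.g. precomputed PEER factors)."""
    t = sheet.table.set_index("sample_id")
    missing = [s for s in sample_ids if s not in t.index]
    if missing:
        raise ValidationError(f"samples not in sheet: {missing[:3]}")
    cols = {}
    for c in CLINICAL_COVARIATES:
        if c in t.columns:
            cols[c] = t.loc[sample_ids, c].to_numpy(dtype=float)
    df = pd.DataFrame(cols, index=sample_ids)
    if pcs is not None:
        ind = t.loc[sample_ids, "individual_id"]
        for c in pcs.columns:
            df[c] = pcs.loc[ind, c].to_numpy()
    if hidden is not None:
        for c in hidden.columns:
            df[c] = hidden.loc[sample_ids, c].to_numpy()
    if df.isna().any().any():
        raise ValidationError("covariate matrix contains missing values")
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        logger.warning("dropping constant covariate columns: %s", const)
        df = df.drop(columns=const)
    return df


def _ols(X: np.ndarray, y: np.ndarray):
    """(beta, se, df, rank) for OLS; se computed from (X'X)^-1 * sigma^2."""
    n, p = X.shape
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p or n <= p:
        return beta, None, n - p, rank
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv), 0, None) * sigma2)
    return beta, se, n - p, rank


def interaction_scan(expr: ExpressionMatrix, geno: GenotypeMatrix,
                     fraction: pd.Series, covs: pd.DataFrame,
                     pairs: list[CisPair], status_context: str,
                     sample_individuals: list[str] | None = None
                     ) -> list[InteractionScanResult]:
    """Fit the G x fraction interaction OLS for every cis pair within one
    disease-status context.  Missing genotypes are handled complete-case
    per fit.

    Samples are the index of ``covs``; ``sample_individuals`` maps each
    sample to its genotype-matrix individual (defaults to the sample ids
    themselves).
    """
    samples = list(covs.index)
    sidx = expr.sample_index()
    missing = [s for s in samples if s not in sidx]
    if missing:
        raise ValidationError(f"samples without expression: {missing[:3]}")
    Y = expr.log2p1()[:, [sidx[s] for s in samples]]
    f = fraction.reindex(samples).to_numpy(dtype=float)
    if np.isnan(f).any():
        raise ValidationError("fraction missing for some samples")
    if sample_individuals is None:
        sample_individuals = samples
    return _scan_core(Y, expr.gene_index(), geno, geno.variant_index(), f,
                      covs.to_numpy(dtype=float), pairs, status_context,
                      samples, sample_individuals)


def _scan_core(Y, gidx, geno, vindex, f, C, pairs, status_context, samples,
               sample_individuals):
    g_rows = {ind: i for i, ind in enumerate(geno.individuals)}
    absent = [i for i in sample_individuals if i not in g_rows]
    if absent:
        raise ValidationError(f"individuals without genotypes: {absent[:3]}")
    rows = np.array([g_rows[i] for i in sample_individuals])
    n = len(samples)
    ones = np.ones(n)
    results = []
    for pair in pairs:
        gi = gidx.get(pair.gene_id)
        vj = vindex.get(pair.variant_id)
        if gi is None or vj is None:
            results.append(InteractionScanResult(
                pair, status_context, na_reason="missing gene or variant"))
            continue
        G = geno.dosages[rows, vj]
        mask = ~np.isnan(G)
        Gm, fm, Cm, ym = G[mask], f[mask], C[mask], Y[gi][mask]
        X = np.column_stack([ones[mask], Cm, Gm, fm, Gm * fm])
        beta, se, df, rank = _ols(X, ym)
        if se is None or df < 1:
            results.append(InteractionScanResult(
                pair, status_context, na_reason="rank-deficient design"))
            continue
        b_gxf, se_gxf = beta[-1], se[-1]
        tval = b_gxf / se_gxf if se_gxf > 0 else np.nan
        if np.isnan(tval):
            results.append(InteractionScanResult(
                pair, status_context, na_reason="zero-variance interaction"))
            continue
        p = 2.0 * stats.t.sf(abs(tval), df)
        results.append(InteractionScanResult(
            pair, status_context, beta_g=float(beta[-3]),
            beta_f=float(beta[-2]), beta_gxf=float(b_gxf),
            se_gxf=float(se_gxf), t_gxf=float(tval), p_nominal=float(p)))
    return results


def _simes(pvals: np.ndarray) -> float:
    p = np.sort(pvals)
    m = p.size
    return float(min(1.0, (p * m / np.arange(1, m + 1)).min()))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    adj = pvals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hierarchical_adjust(results: list[InteractionScanResult],
                        alpha: float = 0.01) -> list[InteractionScanResult]:
    """Two-level Simes + BH correction; fills p_adjusted and significant in
    place (and returns the list).  NA pairs are excluded from all counts."""
    if not results:
        raise ValidationError("hierarchical_adjust: empty result list")
    ok = [r for r in results if not r.na_reason and np.isfinite(r.p_nominal)]
    if not ok:
        raise ValidationError("hierarchical_adjust: no testable pairs")
    genes = sorted({r.pair.gene_id for r in ok})
    by_gene = {g: [] for g in genes}
    for r in ok:
        by_gene[r.pair.gene_id].append(r)
    gene_p = np.array([_simes(np.array([r.p_nominal for r in by_gene[g]]))
                       for g in genes])
    gene_q = _bh_adjust(gene_p)
    G = len(genes)
    passing = {g for g, q in zip(genes, gene_q) if q <= alpha}
    R = len(passing)
    gene_q_map = dict(zip(genes, gene_q))
    for g in genes:
        rs = by_gene[g]
        within = _bh_adjust(np.array([r.p_nominal for r in rs]))
        if g in passing:
            # scaled so that p_adjusted <= alpha  <=>  within-BH <= (R/G) alpha
            adj = np.minimum(within * G / R, 1.0)
        else:
            adj = np.maximum(np.minimum(within * G / max(R, 1), 1.0),
                             gene_q_map[g])
        for r, a in zip(rs, adj):
            r.p_adjusted = float(a)
            r.significant = bool(g in passing and a <= alpha)
    for r in results:
        if r.na_reason:
            r.p_adjusted = np.nan
            r.significant = False
    logger.info("hierarchical_adjust: %d/%d genes pass at alpha=%g", R, G, alpha)
    return results


def select_top_eqtl_per_gene(results: list[InteractionScanResult]
                             ) -> list[CisPair]:
    """The most significant pair per gene among significant pairs; ties by
    smaller |tss_distance|, then lexicographic variant id."""
    best: dict[str, InteractionScanResult] = {}
    for r in results:
        if not r.significant:
            continue
        g = r.pair.gene_id
        key = (r.p_nominal, abs(r.pair.tss_distance), r.pair.variant_id)
        cur = best.get(g)
        if cur is None or key < (cur.p_nominal, abs(cur.pair.tss_distance),
                                 cur.pair.variant_id):
            best[g] = r
    return [best[g].pair for g in sorted(best)]


def run_interaction_scan(expr: ExpressionMatrix, geno: GenotypeMatrix,
                         fractions: CellFractionTable, sheet: SampleSheet,
                         genes: list[GeneAnnotation], *, status: int,
                         window: int = 1_000_000, alpha: float = 0.01,
                         n_pcs: int | None = None,
                         hidden: pd.DataFrame | None = None,
                         pairs: list[CisPair] | None = None
                         ) -> list[InteractionScanResult]:
    """Orchestrate the stage-1 scan for one disease status (tumor samples
    use 2 genotype PCs by default, normal samples 3)."""
    samples = [s for s in sheet.samples_for_status(status)
               if s in set(expr.sample_ids)]
    if not samples:
        raise ValidationError(f"no samples with status {status}")
    if n_pcs is None:
        n_pcs = 2 if status == 1 else 3
    pcs = genotype_pcs(geno, n_pcs) if n_pcs else None
    covs = build_covariates(sheet, samples, pcs=pcs, hidden=hidden)
    if pairs is None:
        pairs = enumerate_cis_pairs(geno.variants, genes, window)
    fraction = fractions.column("epithelial")
    t = sheet.table.set_index("sample_id")
    sample_individuals = list(t.loc[samples, "individual_id"])
    sidx = expr.sample_index()
    Y = expr.log2p1()[:, [sidx[s] for s in samples]]
    results = _scan_core(Y, expr.gene_index(), geno, geno.variant_index(),
                         fraction.reindex(samples).to_numpy(dtype=float),
                         covs.to_numpy(dtype=float), pairs,
                         "tumor" if status == 1 else "normal", samples,
                         sample_individuals=sample_individuals)
    return hierarchical_adjust(results, alpha=alpha)
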