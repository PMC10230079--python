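import numpy as np
import pandas as pd
import pytest

from cseqtl import (
    GeneAnnotation,
    GenotypeMatrix,
    VariantRecord,
    enumerate_cis_pairs,
    genotype_pcs,
    hierarchical_adjust,
    interaction_scan,
    select_top_eqtl_per_gene,
)
from cseqtl.core import ExpressionMatrix
from cseqtl.scan import CisPair, InteractionScanResult


# ---------------------------------------------------------------- cis pairs

def test_cis_pair_distance_strand_aware():
    v = [VariantRecord("v1", "chr1", 1_000_500, "A", "G")]
    plus = [GeneAnnotation("Gp", "chr1", 1_000_000, 1_020_000, "+")]
    minus = [GeneAnnotation("Gm", "chr1", 1_000_000, 980_000, "-")]
    assert enumerate_cis_pairs(v, plus, 1_000_000)[0].tss_distance == 500
    assert enumerate_cis_pairs(v, minus, 1_000_000)[0].tss_distance == -500


def test_cis_pair_window_and_chromosome_bounds():
    v = [VariantRecord("v1", "chr1", 3_000_000, "A", "G"),
         VariantRecord("v2", "chr2", 1_000_100, "A", "G")]
    genes = [GeneAnnotation("G1", "chr1", 1_000_000, 1_020_000, "+")]
    assert enumerate_cis_pairs(v, genes, 1_000_000) == []


# ---------------------------------------------------------------------- PCA

def _two_cluster_genotypes(rng, n=40, m=60):
    base = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    cluster = np.repeat([0, 1], n // 2)
    base[cluster == 1, : m // 2] = rng.binomial(
        2, 0.8, size=(n // 2, m // 2))
    variants = [VariantRecord(f"v{j}", "chr1", 100 + j, "A", "G")
                for j in range(m)]
    return GenotypeMatrix([f"I{i}" for i in range(n)], variants, base), cluster


def test_genotype_pcs_recover_planted_structure(rng):
    geno, cluster = _two_cluster_genotypes(rng)
    pcs = genotype_pcs(geno, 3)
    pc1 = pcs["PC1"].to_numpy()
    assert np.sign(pc1[cluster == 0].mean()) != np.sign(pc1[cluster == 1].mean())
    # orthonormality
    U = pcs.to_numpy()
    np.testing.assert_allclose(U.T @ U, np.eye(3), atol=1e-8)
    # deterministic sign convention
    for j in range(3):
        assert U[np.argmax(np.abs(U[:, j])), j] > 0


def test_genotype_pcs_constant_variant_skipped(rng):
    geno, _ = _two_cluster_genotypes(rng, n=20, m=10)
    geno.dosages[:, 0] = 2.0  # monomorphic
    pcs = genotype_pcs(geno, 2)
    assert np.isfinite(pcs.to_numpy()).all()


def test_genotype_pcs_k_validation(rng):
    geno, _ = _two_cluster_genotypes(rng, n=20, m=10)
    with pytest.raises(ValueError):
        genotype_pcs(geno, 0)
    with pytest.raises(ValueError):
        genotype_pcs(geno, 20)


# --------------------------------------------------------------------- scan

def _scan_instance(rng, n=30, beta_gxf=0.0):
    G = rng.binomial(2, 0.4, n).astype(float)
    f = rng.beta(2, 2, n)
    c = rng.normal(size=n)
    y = 0.5 + 0.3 * c + 0.2 * G + 0.4 * f + beta_gxf * G * f + rng.normal(0, 1, n)
    tpm = np.clip(np.exp2(y) - 1, 0, None)
    samples = [f"I{i}" for i in range(n)]
    expr = ExpressionMatrix(["G1"], samples, tpm[None, :])
    geno = GenotypeMatrix(samples,
                          [VariantRecord("v1", "chr1", 1000, "A", "G")],
                          G[:, None])
    covs = pd.DataFrame({"c": c}, index=samples)
    fraction = pd.Series(f, index=samples)
    pairs = [CisPair("v1", "G1", 500)]
    return expr, geno, fraction, covs, pairs, y


def test_interaction_scan_matches_normal_equations_oracle(rng):
    expr, geno, fraction, covs, pairs, y = _scan_instance(rng)
    res = interaction_scan(expr, geno, fraction, covs, pairs, "tumor")[0]
    X = np.column_stack([np.ones(30), covs["c"], geno.dosages[:, 0],
                         fraction, geno.dosages[:, 0] * fraction])
    yy = expr.log2p1()[0]
    beta = np.linalg.solve(X.T @ X, X.T @ yy)  # brute-force normal equations
    assert res.beta_gxf == pytest.approx(beta[-1], abs=1e-8)
    assert res.beta_g == pytest.approx(beta[2], abs=1e-8)
    resid = yy - X @ beta
    s2 = resid @ resid / (30 - 5)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
    assert res.se_gxf == pytest.approx(se, abs=1e-8)


def test_interaction_scan_constant_fraction_flagged_na(rng):
    expr, geno, _, covs, pairs, _ = _scan_instance(rng)
    const = pd.Series(0.5, index=covs.index)
    res = interaction_scan(expr, geno, const, covs, pairs, "tumor")[0]
    assert res.na_reason == "rank-deficient design"
    assert not res.significant


def test_interaction_scan_affine_covariate_invariance(rng):
    expr, geno, fraction, covs, pairs, _ = _scan_instance(rng)
    t1 = interaction_scan(expr, geno, fraction, covs, pairs, "tumor")[0].t_gxf
    covs2 = covs * 7.5 - 3.0
    t2 = interaction_scan(expr, geno, fraction, covs2, pairs, "tumor")[0].t_gxf
    assert t1 == pytest.approx(t2, abs=1e-8)


def test_interaction_scan_complete_case_on_missing_genotypes(rng):
    expr, geno, fraction, covs, pairs, _ = _scan_instance(rng, n=30)
    geno.dosages[0, 0] = np.nan
    res = interaction_scan(expr, geno, fraction, covs, pairs, "tumor")[0]
    keep = slice(1, None)
    X = np.column_stack([np.ones(29), covs["c"][keep], geno.dosages[keep, 0],
                         fraction[keep], geno.dosages[keep, 0] * fraction[keep]])
    yy = expr.log2p1()[0][keep]
    beta = np.linalg.solve(X.T @ X, X.T @ yy)
    assert res.beta_gxf == pytest.approx(beta[-1], abs=1e-8)


# ------------------------------------------------------- hierarchical adjust

def _result(gene, vid, p, dist=0):
    return InteractionScanResult(CisPair(vid, gene, dist), "tumor", p_nominal=p)


def two_step_oracle(results, alpha):
    """Naive independent reimplementation of Simes + two-level BH."""
    df = pd.DataFrame([(r.pair.gene_id, r.pair.variant_id, r.p_nominal)
                       for r in results], columns=["gene", "snp", "p"])
    gene_p = {}
    for g, sub in df.groupby("gene"):
        ps = np.sort(sub["p"].to_numpy())
        gene_p[g] = min((ps * len(ps) / (np.arange(len(ps)) + 1)).min(), 1.0)
    genes = sorted(gene_p)
    G = len(genes)
    ps = np.array([gene_p[g] for g in genes])
    order = np.argsort(ps)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if ps[idx] <= rank / G * alpha:
            k_max = rank
    selected_genes = {genes[i] for i in order[:k_max]}
    R = len(selected_genes)
    selected = set()
    for g in selected_genes:
        sub = df[df.gene == g].sort_values("p")
        m = len(sub)
        level = R / G * alpha
        k2 = 0
        for rank, p in enumerate(sub["p"], start=1):
            if p <= rank / m * level:
                k2 = rank
        selected |= {(g, s) for s in sub["snp"].iloc[:k2]}
    return selected


def test_hierarchical_adjust_single_pair_degenerate():
    res = hierarchical_adjust([_result("G1", "v1", 0.004)], alpha=0.01)
    assert res[0].p_adjusted == pytest.approx(0.004)
    assert res[0].significant


def test_hierarchical_adjust_all_ones_nothing_significant():
    results = [_result(f"G{i}", f"v{j}", 1.0) for i in range(4) for j in range(3)]
    out = hierarchical_adjust(results, alpha=0.01)
    assert not any(r.significant for r in out)


def test_hierarchical_adjust_matches_two_step_oracle(rng):
    results = []
    for i in range(20):
        for j in range(5):
            # plant signal in two genes
            p = rng.uniform(1e-6, 5e-4) if i < 2 else rng.uniform(0.01, 1.0)
            results.append(_result(f"G{i:02d}", f"v{j}", float(p)))
    out = hierarchical_adjust(results, alpha=0.01)
    got = {(r.pair.gene_id, r.pair.variant_id) for r in out if r.significant}
    assert got == two_step_oracle(results, 0.01)


def test_hierarchical_adjust_na_pairs_excluded():
    na = InteractionScanResult(CisPair("vx", "G1", 0), "tumor",
                               na_reason="rank-deficient design")
    out = hierarchical_adjust([_result("G1", "v1", 0.004), na], alpha=0.01)
    assert not out[1].significant and np.isnan(out[1].p_adjusted)


# ------------------------------------------------------------ top selection

def test_select_top_eqtl_tie_breaks():
    r1 = _result("G1", "vb", 0.001, dist=2000)
    r2 = _result("G1", "va", 0.01, dist=100)
    r3 = _result("G2", "vc", 0.001, dist=2000)
    r4 = _result("G2", "vd", 0.001, dist=500)   # tie in p: closer wins
    r5 = _result("G3", "vf", 0.001, dist=500)
    r6 = _result("G3", "ve", 0.001, dist=-500)  # tie in p and |dist|: id wins
    for r in (r1, r2, r3, r4, r5, r6):
        r.significant = True
    rns = _result("G4", "vg", 0.9)              # not significant -> absent
    top = select_top_eqtl_per_gene([r1, r2, r3, r4, r5, r6, rns])
    assert [(p.gene_id, p.variant_id) for p in top] == [
        ("G1", "vb"), ("G2", "vd"), ("G3", "ve")]
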