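import numpy as np
import pandas as pd
import pytest

from cseqtl import (
    ConfigError,
    SimConfig,
    make_truth_table,
    simulate_cohort,
    simulate_expression,
    simulate_fractions,
    simulate_genotypes,
    simulate_sample_sheet,
)
from cseqtl.scan import enumerate_cis_pairs
from cseqtl.simulate import SimTruth, simulate_gene_annotation


def test_genotype_frequencies_match_target_maf():
    cfg = SimConfig(n_individuals=10_000, n_variants=5, n_genes=2,
                    maf_range=(0.3, 0.3), seed=3)
    geno = simulate_genotypes(cfg)
    freqs = geno.dosages.mean(axis=0) / 2.0
    assert np.all(np.abs(freqs - 0.3) < 0.01)


def test_genotypes_deterministic_given_seed():
    cfg = SimConfig(seed=11)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    np.testing.assert_array_equal(a.dosages, b.dosages)


def test_invalid_maf_range_rejected():
    with pytest.raises(ConfigError):
        SimConfig(maf_range=(0.6, 0.7))


def test_every_gene_has_cis_variants():
    cfg = SimConfig(seed=0)
    geno = simulate_genotypes(cfg)
    genes = simulate_gene_annotation(cfg)
    pairs = enumerate_cis_pairs(geno.variants, genes, 1_000_000)
    assert {p.gene_id for p in pairs} == {g.gene_id for g in genes}


def test_fraction_rows_sum_to_one_and_match_beta_moments():
    cfg = SimConfig(n_individuals=500, seed=5,
                    fraction_beta={0: (50.0, 50.0), 1: (50.0, 50.0)})
    sheet = simulate_sample_sheet(cfg)
    tab = simulate_fractions(cfg, sheet)
    np.testing.assert_allclose(tab.fractions.sum(axis=1), 1.0, atol=1e-12)
    assert abs(tab.column("epithelial").mean() - 0.5) < 0.02


def test_fraction_status_means_ordered():
    cfg = SimConfig(n_individuals=500, seed=5,
                    fraction_beta={0: (5.0, 5.0), 1: (8.0, 2.0)})
    sheet = simulate_sample_sheet(cfg)
    tab = simulate_fractions(cfg, sheet)
    epi = tab.column("epithelial")
    status = sheet.table.set_index("sample_id")["status"]
    assert epi[status == 1].mean() > epi[status == 0].mean()


def test_invalid_beta_parameters_rejected():
    with pytest.raises(ConfigError):
        SimConfig(fraction_beta={0: (0.0, 2.0), 1: (2.0, 2.0)})


def test_truth_table_deterministic_allocation():
    cfg = SimConfig(seed=1, label_proportions={"null": 0.9, "shared": 0.0,
                                               "gain": 0.05, "loss": 0.05})
    pairs = [(f"v{i}", f"G{i}") for i in range(1000)]
    truth = make_truth_table(cfg, pairs)
    counts = truth.table.label.value_counts().to_dict()
    assert counts == {"null": 900, "gain": 50, "loss": 50}
    assert (truth.table.loc[truth.table.label == "gain", "beta_gxs"] != 0).all()


def test_truth_table_seed_changes_assignment_not_counts():
    pairs = [(f"v{i}", f"G{i}") for i in range(200)]
    props = {"null": 0.8, "shared": 0.0, "gain": 0.1, "loss": 0.1}
    t1 = make_truth_table(SimConfig(seed=1, label_proportions=props), pairs)
    t2 = make_truth_table(SimConfig(seed=2, label_proportions=props), pairs)
    c1 = t1.table.label.value_counts().to_dict()
    c2 = t2.table.label.value_counts().to_dict()
    assert c1 == c2
    merged = t1.table.merge(t2.table, on=["variant_id", "gene_id"])
    assert (merged.label_x != merged.label_y).any()


def test_truth_invariants_enforced():
    bad = pd.DataFrame([{"variant_id": "v", "gene_id": "g", "label": "gain",
                         "beta_main": 0.0, "beta_gxf": 1.0, "beta_gxs": 0.0}])
    with pytest.raises(Exception):
        SimTruth(bad)


def test_expression_variance_decomposition_under_null():
    # all betas zero, no random intercept, no covariate/fraction effects:
    # per-gene variance of log2(TPM+1) is the noise variance
    cfg = SimConfig(n_individuals=2500, n_variants=10, n_genes=4, seed=9,
                    sd_random_intercept=0.0, n_covariates=0,
                    fraction_effect_sd=0.0, baseline_mean=6.0, sd_noise=1.0,
                    label_proportions={"null": 1.0})
    geno = simulate_genotypes(cfg)
    sheet = simulate_sample_sheet(cfg)
    fr = simulate_fractions(cfg, sheet)
    truth = make_truth_table(cfg)
    expr = simulate_expression(geno, fr, sheet, truth, cfg)
    v = expr.log2p1().var(axis=1)
    np.testing.assert_allclose(v, 1.0, rtol=0.08)


def test_expression_status_effect_read_off():
    # beta_gxs = 1 with no other effect sources: tumor - normal = G exactly
    cfg = SimConfig(n_individuals=30, n_variants=10, n_genes=4, seed=2,
                    sd_random_intercept=0.0, sd_noise=0.0, n_covariates=0,
                    fraction_effect_sd=0.0, baseline_sd=0.0, baseline_mean=8.0,
                    beta_gxf=0.0, beta_gxs=1.0,
                    label_proportions={"null": 0.0, "gain": 1.0})
    geno = simulate_genotypes(cfg)
    sheet = simulate_sample_sheet(cfg)
    fr = simulate_fractions(cfg, sheet)
    truth = make_truth_table(cfg)
    expr = simulate_expression(geno, fr, sheet, truth, cfg)
    y = expr.log2p1()
    t = sheet.table
    row = truth.table.iloc[0]
    gi = expr.gene_index()[row.gene_id]
    vj = geno.variant_index()[row.variant_id]
    for i, ind in enumerate(geno.individuals):
        st = t[t.individual_id == ind].set_index("status")["sample_id"]
        sidx = expr.sample_index()
        diff = y[gi, sidx[st[1]]] - y[gi, sidx[st[0]]]
        assert diff == pytest.approx(geno.dosages[i, vj], abs=1e-9)


def test_expression_deterministic_given_seed():
    cfg = SimConfig(n_individuals=25, n_variants=20, n_genes=5, seed=4)
    a = simulate_cohort(cfg).expression
    b = simulate_cohort(cfg).expression
    np.testing.assert_array_equal(a.values, b.values)
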