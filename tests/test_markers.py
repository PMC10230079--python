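import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cseqtl import (
    ExpressionMatrix,
    SampleSheet,
    ValidationError,
    cox_adjusted_hr,
    genotype_grouping,
    logrank_test,
    paired_de,
    promoter_enrichment,
)
from cseqtl.scan import CisPair


# ----------------------------------------------------------- test oracles

def logrank_oracle(time, event, group):
    """Direct O-E / V evaluation of the two-group log-rank statistic."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    oe, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return oe ** 2 / var


def cox_newton_oracle(time, event, x):
    """Newton iteration on the (no-ties) Cox partial likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(50):
        u, i = 0.0, 0.0
        for t in time[event == 1]:
            risk = time >= t
            w = np.exp(beta * x[risk])
            xb = (w * x[risk]).sum() / w.sum()
            x2b = (w * x[risk] ** 2).sum() / w.sum()
            xi = x[(time == t) & (event == 1)][0]
            u += xi - xb
            i += x2b - xb ** 2
        step = u / i
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


# -------------------------------------------------------------------- DE

def _paired_expr(rng, n_genes=20, n_pairs=30, shifted=(0, 1, 2), fold=2.0,
                 noise=0.3):
    rows = []
    for i in range(n_pairs):
        rows.append(dict(sample_id=f"I{i}_T", individual_id=f"I{i}", status=1))
        rows.append(dict(sample_id=f"I{i}_N", individual_id=f"I{i}", status=0))
    sheet = SampleSheet(pd.DataFrame(rows))
    base = rng.normal(5, 0.5, size=(n_genes, n_pairs))
    noise_t = rng.normal(0, noise, size=(n_genes, n_pairs))
    noise_n = rng.normal(0, noise, size=(n_genes, n_pairs))
    y_t, y_n = base + noise_t, base + noise_n
    for g in shifted:
        y_t[g] += np.log2(fold)
    samples, vals = [], []
    for i in range(n_pairs):
        samples += [f"I{i}_T", f"I{i}_N"]
        vals.append(np.exp2(y_t[:, i]) - 1)
        vals.append(np.exp2(y_n[:, i]) - 1)
    expr = ExpressionMatrix([f"G{g}" for g in range(n_genes)], samples,
                            np.clip(np.array(vals).T, 0, None))
    return expr, sheet


def test_paired_de_detects_planted_shift(rng):
    expr, sheet = _paired_expr(rng)
    res = paired_de(expr, sheet)
    calls = {r.gene_id: r.call for r in res}
    assert all(calls[f"G{g}"] == "up" for g in (0, 1, 2))
    assert all(c == "ns" for gid, c in calls.items()
               if gid not in {"G0", "G1", "G2"})
    for r in res:
        if r.call == "up":
            assert r.q < 0.05 and r.fold_change > 1.2


def test_paired_de_fold_change_gate(rng):
    # consistent but tiny shift: Wilcoxon significant, FC gate fails -> ns
    expr, sheet = _paired_expr(rng, n_pairs=60, shifted=(0,), fold=1.05,
                               noise=0.03)
    res = {r.gene_id: r for r in paired_de(expr, sheet)}
    assert res["G0"].q < 0.05 and res["G0"].call == "ns"


def test_paired_de_too_few_pairs_flagged(rng):
    expr, sheet = _paired_expr(rng, n_pairs=4)
    res = paired_de(expr, sheet)
    assert all(r.na_reason for r in res)


def test_paired_de_q_monotone_in_p(rng):
    expr, sheet = _paired_expr(rng)
    res = [r for r in paired_de(expr, sheet) if np.isfinite(r.q)]
    res.sort(key=lambda r: r.p)
    qs = [r.q for r in res]
    assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))


# ------------------------------------------------------------- enrichment

def _pairs(n, n_promoter, window=2000):
    return ([CisPair(f"p{i}", "G", 500) for i in range(n_promoter)]
            + [CisPair(f"d{i}", "G", 50_000) for i in range(n - n_promoter)])


def test_promoter_enrichment_matches_fisher_oracle():
    orr, p = promoter_enrichment(_pairs(100, 30), _pairs(100, 10))
    assert orr == pytest.approx(30 * 90 / (70 * 10), abs=1e-9)
    # independent hypergeometric enumeration of the two-sided Fisher p
    p_oracle = stats.hypergeom(200, 40, 100)
    probs = np.array([p_oracle.pmf(k) for k in range(41)])
    p_two = probs[probs <= probs[30] * (1 + 1e-12)].sum()
    assert p == pytest.approx(p_two, rel=1e-8)


def test_promoter_enrichment_identical_proportions():
    orr, p = promoter_enrichment(_pairs(50, 10), _pairs(50, 10))
    assert orr == pytest.approx(1.0)


def test_promoter_enrichment_zero_cell_corrected():
    orr, _ = promoter_enrichment(_pairs(20, 20), _pairs(20, 5))
    assert np.isfinite(orr) and orr > 1


def test_promoter_enrichment_empty_rejected():
    with pytest.raises(ValidationError):
        promoter_enrichment([], _pairs(5, 1))


# --------------------------------------------------------------- survival

TOY8 = dict(
    time=[5.0, 8.0, 12.0, 20.0, 3.0, 9.0, 15.0, 25.0],
    event=[1, 1, 0, 1, 1, 1, 1, 0],
    group=[0, 0, 0, 0, 1, 1, 1, 1],
)


def test_logrank_matches_direct_oracle():
    stat, p = logrank_test(**TOY8)
    oracle = logrank_oracle(TOY8["time"], TOY8["event"], TOY8["group"])
    assert stat == pytest.approx(oracle, abs=1e-6)
    assert p == pytest.approx(stats.chi2.sf(oracle, 1), abs=1e-6)


def test_logrank_identical_groups_is_null():
    t = [3.0, 6.0, 9.0, 3.0, 6.0, 9.0]
    e = [1, 1, 1, 1, 1, 1]
    g = [0, 0, 0, 1, 1, 1]
    stat, p = logrank_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_logrank_asymptotic_matches_permutation_oracle():
    rng = np.random.default_rng(8)
    n = 50
    group = rng.integers(0, 2, n)
    time = rng.exponential(np.where(group == 1, 14.0, 10.0))
    event = (rng.random(n) < 0.8).astype(int)
    stat, p_asym = logrank_test(time, event, group)
    count = 0
    B = 5000
    for _ in range(B):
        count += logrank_oracle(time, event, rng.permutation(group)) >= stat
    p_perm = (1 + count) / (1 + B)
    assert abs(p_perm - p_asym) < 0.02


def test_cox_matches_newton_oracle():
    time = [2.0, 4.0, 6.0, 9.0, 13.0, 17.0]
    event = [1, 1, 1, 1, 0, 1]
    group = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
    res = cox_adjusted_hr(time, event, group)
    beta = cox_newton_oracle(time, event, group)
    assert np.log(res.hr) == pytest.approx(beta, abs=1e-6)
    assert res.ci_low <= res.hr <= res.ci_high


def test_cox_and_logrank_agree_in_direction(rng):
    for _ in range(5):
        n = 80
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.where(g == 1, 6.0, 12.0))
        e = np.ones(n, dtype=int)
        res = cox_adjusted_hr(t, e, g)
        assert res.hr > 1  # group 1 has higher hazard by construction


def test_cox_separation_flagged():
    # group perfectly separates event order: monotone likelihood
    time = np.arange(1.0, 11.0)
    event = np.ones(10, int)
    group = np.array([1.0] * 5 + [0.0] * 5)
    res = cox_adjusted_hr(time, event, group)
    assert res.na_reason or res.ci_high > 100  # flagged or unbounded CI


def test_km_curve_matches_hand_computed_product_limit():
    from cseqtl import km_curve

    df = km_curve([5, 8, 12, 20, 3], [1, 1, 0, 1, 1])
    # product-limit by hand: 4/5, then 3/4, then 2/3 -> 0.8, 0.6, 0.4;
    # censoring at 12 leaves the estimate flat; last event drops it to 0
    np.testing.assert_allclose(df["survival"],
                               [1.0, 0.8, 0.6, 0.4, 0.4, 0.0], atol=1e-12)
    assert list(df["time"]) == [0.0, 3.0, 5.0, 8.0, 12.0, 20.0]


def test_genotype_grouping_rules():
    g = genotype_grouping([0, 1, 2, 0, np.nan])
    np.testing.assert_array_equal(g[:4], [0, 1, 1, 0])
    assert np.isnan(g[4])
    assert len(np.unique(genotype_grouping([0, 0, 0]))) == 1  # untestable
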