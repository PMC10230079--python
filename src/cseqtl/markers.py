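"""Downstream marker analyses: paired differential expression, positional
(promoter) enrichment of gain vs loss eQTLs, and genotype-stratified
survival.

Differential expression: per gene, a paired Wilcoxon signed-rank test on
log2(TPM + 1) across tumor/normal pairs, BH-corrected across genes; a gene
is called "up" if q < 0.05 and the tumor/normal fold change of mean TPM
exceeds 1.2, "down" if q < 0.05 and the fold change is below 0.8.

Survival: patients are grouped by minor/alt-allele carrier status (dominant
model: dosage 0 vs {1, 2}); group differences are tested by the two-group
log-rank test, and hazard ratios with Wald 95% CIs come from a Cox
proportional-hazards model (Efron tie handling) adjusted for age, sex,
smoking, drinking and TNM stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .core import ExpressionMatrix, SampleSheet, ValidationError
from .scan import CisPair

MIN_PAIRS_DE = 6
FC_UP = 1.2
FC_DOWN = 0.8
Q_DE = 0.05

SURVIVAL_COVARIATES = ("age_group", "sex", "smoking", "drinking", "tnm_stage")


@dataclass
class DeResult:
    gene_id: str
    fold_change: float = np.nan  # mean tumor TPM / mean normal TPM
    p: float = np.nan
    q: float = np.nan
    call: str = "ns"  # up | down | ns
    na_reason: str = ""


@dataclass
class SurvivalResult:
    feature_id: str
    logrank_stat: float = np.nan
    logrank_p: float = np.nan
    hr: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_group0: int = 0
    n_group1: int = 0
    na_reason: str = ""


def _bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def paired_de(expr: ExpressionMatrix, sheet: SampleSheet) -> list[DeResult]:
    """Paired Wilcoxon DE with BH correction and the fold-change gate."""
    t = sheet.table
    paired = sheet.paired_individuals()
    tum = t[(t.status == 1) & t.individual_id.isin(paired)] \
        .set_index("individual_id")["sample_id"]
    nor = t[(t.status == 0) & t.individual_id.isin(paired)] \
        .set_index("individual_id")["sample_id"]
    sidx = expr.sample_index()
    inds = [i for i in paired if tum[i] in sidx and nor[i] in sidx]
    tcols = [sidx[tum[i]] for i in inds]
    ncols = [sidx[nor[i]] for i in inds]
    logY = expr.log2p1()
    results = []
    pvals, testable = [], []
    for gi, gene in enumerate(expr.gene_ids):
        yt, yn = logY[gi, tcols], logY[gi, ncols]
        mt, mn = expr.values[gi, tcols].mean(), expr.values[gi, ncols].mean()
        fc = mt / mn if mn > 0 else np.inf if mt > 0 else np.nan
        if len(inds) < MIN_PAIRS_DE:
            results.append(DeResult(gene, fc, na_reason="fewer than 6 pairs"))
            continue
        diff = yt - yn
        if np.allclose(diff, 0):
            results.append(DeResult(gene, fc, p=1.0))
            pvals.append(1.0)
            testable.append(len(results) - 1)
            continue
        p = float(stats.wilcoxon(yt, yn, zero_method="wilcox").pvalue)
        results.append(DeResult(gene, fc, p=p))
        pvals.append(p)
        testable.append(len(results) - 1)
    if testable:
        qs = _bh(np.array(pvals))
        for idx, q in zip(testable, qs):
            r = results[idx]
            r.q = float(q)
            if q < Q_DE and r.fold_change > FC_UP:
                r.call = "up"
            elif q < Q_DE and r.fold_change < FC_DOWN:
                r.call = "down"
    return results


def promoter_enrichment(gain: list[CisPair], loss: list[CisPair],
                        promoter_window: int = 2_000) -> tuple[float, float]:
    """Odds ratio (Haldane 0.5 correction on zero cells) and two-sided
    Fisher exact p for gain vs loss eQTLs falling within the promoter
    window of their paired gene's TSS."""
    if not gain or not loss:
        raise ValidationError("both gain and loss lists must be non-empty")
    a = sum(abs(p.tss_distance) <= promoter_window for p in gain)
    b = len(gain) - a
    c = sum(abs(p.tss_distance) <= promoter_window for p in loss)
    d = len(loss) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    return float(orr), float(p)


def genotype_grouping(dosages) -> np.ndarray:
    """Dominant (carrier) grouping: 0 = non-carrier, 1 = carries >= 1 alt
    allele; missing dosage -> NaN (excluded)."""
    d = np.asarray(dosages, dtype=float)
    group = np.where(np.isnan(d), np.nan, (d >= 1).astype(float))
    return group


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=float)
    ok = ~np.isnan(group)
    time, event, group = time[ok], event[ok], group[ok]
    if len(np.unique(group)) != 2:
        raise ValidationError("log-rank test needs two non-empty groups")
    if event.sum() < 1:
        raise ValidationError("log-rank test needs at least one event")
    g0, g1 = np.unique(group)
    res = _ll_logrank(time[group == g0], time[group == g1],
                      event_observed_A=event[group == g0],
                      event_observed_B=event[group == g1])
    return float(res.test_statistic), float(res.p_value)


def cox_adjusted_hr(time, event, group, covs: pd.DataFrame | None = None,
                    feature_id: str = "") -> SurvivalResult:
    """Covariate-adjusted Cox HR for the binary genotype group (Efron ties,
    Wald 95% CI).  Non-convergence or complete separation is NA-flagged."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=float)
    df = pd.DataFrame({"time": time, "event": event, "group": group})
    if covs is not None:
        for c in covs.columns:
            df[c] = np.asarray(covs[c], dtype=float)
    df = df.dropna()
    n0 = int((df.group == 0).sum())
    n1 = int((df.group == 1).sum())
    if n0 == 0 or n1 == 0:
        return SurvivalResult(feature_id, n_group0=n0, n_group1=n1,
                              na_reason="one genotype group is empty")
    if (df["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    n_params = df.shape[1] - 2
    if df["event"].sum() < n_params:
        return SurvivalResult(feature_id, n_group0=n0, n_group1=n1,
                              na_reason="fewer events than parameters")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
        # non-convergence or monotone likelihood (complete separation)
        return SurvivalResult(feature_id, n_group0=n0, n_group1=n1,
                              na_reason=f"Cox fit failed: {e}")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    z = stats.norm.ppf(0.975)
    return SurvivalResult(
        feature_id,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        n_group0=n0, n_group1=n1,
    )


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates (time, survival probability,
    number at risk), for plotting elsewhere."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    ev = kmf.event_table
    return pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        "n_at_risk": ev["at_risk"].reindex(kmf.survival_function_.index)
        .to_numpy(),
    })


def survival_analysis(geno, sheet: SampleSheet, variant_ids=None
                      ) -> list[SurvivalResult]:
    """Log-rank + adjusted Cox for each variant under the carrier model,
    using each individual's tumor-sample clinical covariates."""
    t = sheet.table
    tum = t[t.status == 1].set_index("individual_id")
    inds = [i for i in tum.index if i in set(geno.individuals)]
    tum = tum.loc[inds]
    ok = tum["surv_time"].notna() & tum["surv_event"].notna()
    tum = tum[ok]
    if tum.empty:
        raise ValidationError("no individuals with survival follow-up")
    g_rows = {ind: i for i, ind in enumerate(geno.individuals)}
    rows = [g_rows[i] for i in tum.index]
    time = tum["surv_time"].to_numpy(dtype=float)
    event = tum["surv_event"].to_numpy(dtype=int)
    covs = tum[[c for c in SURVIVAL_COVARIATES if c in tum.columns]] \
        .reset_index(drop=True)
    vidx = geno.variant_index()
    if variant_ids is None:
        variant_ids = [v.id for v in geno.variants]
    results = []
    for vid in variant_ids:
        d = geno.dosages[rows, vidx[vid]]
        group = genotype_grouping(d)
        obs = group[~np.isnan(group)]
        if len(np.unique(obs)) < 2:
            results.append(SurvivalResult(vid, na_reason="untestable: one group empty"))
            continue
        res = cox_adjusted_hr(time, event, group, covs, feature_id=vid)
        try:
            stat, p = logrank_test(time, event, group)
            res.logrank_stat, res.logrank_p = stat, p
        except ValidationError as e:
            if not res.na_reason:
                res.na_reason = str(e)
        results.append(res)
    return results
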