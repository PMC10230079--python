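"""End-to-end orchestration of the condition-specific eQTL pipeline on a
cohort (synthetic or supplied): variant QC, the two stage-1 interaction
scans, the paired mixed-model stage with permutation p-values, gain/loss
classification, and the downstream marker analyses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as cio
from .core import RunConfig, logger
from .coloc import coloc_pp, finemap_pip, simulate_region_zscores, wakefield_abf
from .lmm import LmmResult, classify_gain_loss, run_condition_lmm
from .markers import paired_de, promoter_enrichment, survival_analysis
from .qc import filter_variants
from .scan import (
    CisPair,
    enumerate_cis_pairs,
    run_interaction_scan,
    select_top_eqtl_per_gene,
)
from .simulate import Cohort, SimConfig, simulate_cohort, write_cohort


@dataclass
class PipelineResult:
    qc_reports: list
    scan_tumor: list
    scan_normal: list
    tumor_top: list[CisPair]
    normal_top: list[CisPair]
    lmm_results: list[LmmResult]
    de_results: list
    survival_results: list
    enrichment: dict
    coloc: dict
    summary: dict


def run_pipeline(cohort: Cohort, run_cfg: RunConfig,
                 out_dir: str | None = None,
                 n_permutations: int | None = None) -> PipelineResult:
    """Run every stage on an in-memory cohort; optionally write all output
    tables under ``out_dir``."""
    B = n_permutations or run_cfg.n_permutations
    geno, reports = filter_variants(cohort.genotypes, run_cfg)
    scan_t = run_interaction_scan(
        cohort.expression, geno, cohort.fractions, cohort.sheet, cohort.genes,
        status=1, window=run_cfg.cis_window_bp, alpha=run_cfg.stage1_alpha)
    scan_n = run_interaction_scan(
        cohort.expression, geno, cohort.fractions, cohort.sheet, cohort.genes,
        status=0, window=run_cfg.cis_window_bp, alpha=run_cfg.stage1_alpha)
    top_t = select_top_eqtl_per_gene(scan_t)
    top_n = select_top_eqtl_per_gene(scan_n)
    union, seen = [], set()
    for p in top_t + top_n:
        key = (p.variant_id, p.gene_id)
        if key not in seen:
            seen.add(key)
            union.append(p)
    logger.info("pipeline: %d tumor-top, %d normal-top, %d union pairs",
                len(top_t), len(top_n), len(union))
    lmm_results = run_condition_lmm(
        cohort.expression, geno, cohort.fractions, cohort.sheet, union,
        n_permutations=B, seed=run_cfg.seed)
    classify_gain_loss(top_t, top_n, lmm_results, alpha=run_cfg.stage2_alpha)

    gain = [r.pair for r in lmm_results if r.label == "gain"]
    loss = [r.pair for r in lmm_results if r.label == "loss"]
    if gain and loss:
        orr, p_enr = promoter_enrichment(gain, loss, run_cfg.promoter_window_bp)
    else:
        orr, p_enr = np.nan, np.nan
    enrichment = {"odds_ratio": orr, "p": p_enr,
                  "promoter_window_bp": run_cfg.promoter_window_bp,
                  "n_gain": len(gain), "n_loss": len(loss)}

    de_results = paired_de(cohort.expression, cohort.sheet)
    surv = survival_analysis(geno, cohort.sheet,
                             [p.variant_id for p in union]) if union else []
    coloc_out = _coloc_demo(cohort, geno, lmm_results, run_cfg)

    summary = {
        "n_variants_pass_qc": geno.n_variants,
        "n_pairs_tumor_scan": len(scan_t),
        "n_significant_tumor": sum(r.significant for r in scan_t),
        "n_significant_normal": sum(r.significant for r in scan_n),
        "n_top_pairs": len(union),
        "n_gain": len(gain),
        "n_loss": len(loss),
        "n_shared": sum(r.label == "shared" for r in lmm_results),
        "n_de_up": sum(r.call == "up" for r in de_results),
        "n_de_down": sum(r.call == "down" for r in de_results),
    }
    result = PipelineResult(reports, scan_t, scan_n, top_t, top_n,
                            lmm_results, de_results, surv, enrichment,
                            coloc_out, summary)
    if out_dir:
        _write_outputs(result, out_dir)
    return result


def _coloc_demo(cohort: Cohort, geno, lmm_results, run_cfg: RunConfig) -> dict:
    """Colocalization + fine-mapping on the strongest condition-specific
    eQTL's cis region, against a simulated GWAS sharing its causal variant.

    Real GWAS summary statistics can be supplied through the CLI instead;
    this keeps the end-to-end run self-contained.
    """
    labeled = [r for r in lmm_results if r.label in ("gain", "loss")]
    if not labeled:
        return {}
    best = min(labeled, key=lambda r: (r.p_empirical, r.pair.variant_id))
    gene = next(g for g in cohort.genes if g.gene_id == best.pair.gene_id)
    region = [v for v in geno.variants
              if abs(v.pos - gene.tss) <= run_cfg.cis_window_bp]
    vidx = geno.variant_index()
    t = cohort.sheet.table
    tum = t[t.status == 1]
    sidx = cohort.expression.sample_index()
    cols = [sidx[s] for s in tum["sample_id"]]
    y = cohort.expression.log2p1()[
        cohort.expression.gene_index()[gene.gene_id], cols]
    g_rows = {ind: i for i, ind in enumerate(geno.individuals)}
    rows = [g_rows[i] for i in tum["individual_id"]]
    betas, ses, ids = [], [], []
    for v in region:
        G = geno.dosages[rows, vidx[v.id]]
        ok = ~np.isnan(G)
        if ok.sum() < 10 or np.nanstd(G) == 0:
            continue
        X = np.column_stack([np.ones(ok.sum()), G[ok]])
        beta, rss, rank, _ = np.linalg.lstsq(X, y[ok], rcond=None)
        if rank < 2:
            continue
        resid = y[ok] - X @ beta
        sig2 = resid @ resid / (ok.sum() - 2)
        se = float(np.sqrt(sig2 * np.linalg.inv(X.T @ X)[1, 1]))
        betas.append(float(beta[1]))
        ses.append(se)
        ids.append(v.id)
    if len(ids) < 2:
        return {}
    abf_eqtl = wakefield_abf(np.array(betas), np.array(ses))
    causal = ids.index(best.pair.variant_id) if best.pair.variant_id in ids else \
        int(np.argmax(abf_eqtl))
    rng = np.random.default_rng(np.random.SeedSequence([run_cfg.seed, 7]))
    z_gwas = simulate_region_zscores(len(ids), causal, 8.0, 0.0, rng)
    abf_gwas = wakefield_abf(z_gwas * 0.05, np.full(len(ids), 0.05))
    cres = coloc_pp(abf_eqtl, abf_gwas, run_cfg.p1, run_cfg.p2, run_cfg.p12)
    fres = finemap_pip(abf_eqtl, ids, level=0.99)
    return {"pair": best.pair, "coloc": cres, "finemap": fres,
            "variant_ids": ids}


def _write_outputs(res: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)

    def w(records, name):
        cio.write_results_table(records, os.path.join(out_dir, name))

    w(res.qc_reports, "qc_report.tsv")
    w(res.scan_tumor, "scan_tumor.tsv")
    w(res.scan_normal, "scan_normal.tsv")
    w(res.tumor_top + res.normal_top, "top_eqtls.tsv")
    w(res.lmm_results, "lmm_results.tsv")
    w(res.de_results, "de_results.tsv")
    w(res.survival_results, "survival.tsv")
    pd.DataFrame([res.enrichment]).to_csv(
        os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False)
    if res.coloc:
        c = res.coloc["coloc"]
        pd.DataFrame([{
            "variant_id": res.coloc["pair"].variant_id,
            "gene_id": res.coloc["pair"].gene_id,
            "pp0": c.pp0, "pp1": c.pp1, "pp2": c.pp2,
            "pp3": c.pp3, "pp4": c.pp4, "n_variants": c.n_variants,
        }]).to_csv(os.path.join(out_dir, "coloc.tsv"), sep="\t", index=False)
        f = res.coloc["finemap"]
        pd.DataFrame({
            "variant_id": f.variant_ids, "pip": f.pip,
            "in_credible_set": [v in set(f.credible_set) for v in f.variant_ids],
        }).to_csv(os.path.join(out_dir, "finemap.tsv"), sep="\t", index=False)
    else:
        for name in ("coloc.tsv", "finemap.tsv"):
            pd.DataFrame().to_csv(os.path.join(out_dir, name), sep="\t",
                                  index=False)
    pd.DataFrame([res.summary]).to_csv(
        os.path.join(out_dir, "summary.tsv"), sep="\t", index=False)


def run_all_synthetic(sim_cfg: SimConfig | None = None,
                      run_cfg: RunConfig | None = None,
                      out_dir: str | None = None) -> PipelineResult:
    """Simulate the default synthetic cohort and run every stage on it."""
    sim_cfg = sim_cfg or SimConfig()
    run_cfg = run_cfg or RunConfig(seed=sim_cfg.seed, n_permutations=200)
    cohort = simulate_cohort(sim_cfg)
    if out_dir:
        write_cohort(cohort, os.path.join(out_dir, "inputs"))
    return run_pipeline(cohort, run_cfg, out_dir=out_dir)
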