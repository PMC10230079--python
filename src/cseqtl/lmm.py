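"""Stage 2: the paired linear mixed model with a genotype x disease-status
interaction, permutation-based empirical p-values, and gain/loss
classification of condition-specific eQTLs.

Model (per top eQTL pair), on log2(TPM + 1):

    y ~ genotype + status + genotype x status
        + sum_k (covariate_k + status x covariate_k) + (1 | individual)

with status coding tumor = 1, normal = 0.  Two models are fitted by maximum
likelihood — with and without the genotype x status term — and the primary
interaction test is the 1-df likelihood-ratio chi-square between them (a
Wald test on the interaction coefficient is reported alongside).

Fitting exploits the paired structure: each individual contributes exactly
one tumor and one normal observation, so the orthonormal within-pair
rotation m = (y_T + y_N)/sqrt(2), d = (y_T - y_N)/sqrt(2) decorrelates the
random intercept.  Var(m) = sigma_e^2 + 2 sigma_u^2 and Var(d) = sigma_e^2,
independent, which reduces ML estimation to a one-dimensional concentrated
likelihood in the variance ratio r = Var(d)/Var(m) in (0, 1] solved by
bounded scalar minimisation over log r (the r = 1 boundary, sigma_u = 0, is
checked explicitly).  This makes the permutation null — hundreds of refits
per pair — affordable.

The permutation scheme swaps the tumor/normal status labels within each
individual independently with probability 1/2 (observations keep their
expression values and observation-level covariates such as the epithelial
fraction; the status column and every status x covariate column are rebuilt
from the relabeling).  This preserves the pairing structure, which is the
exchangeability that the no-interaction null licenses.

    p_empirical = (1 + #{T_b >= T_obs}) / (1 + B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .core import (
    CellFractionTable,
    ConfigError,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleSheet,
    ValidationError,
    logger,
)
from .scan import CisPair, build_covariates, genotype_pcs

_SQRT2 = np.sqrt(2.0)
_LOG_R_MIN = -18.0


@dataclass
class LmmResult:
    pair: CisPair
    beta_g: float = np.nan
    beta_status: float = np.nan
    beta_gxs: float = np.nan
    se_gxs: float = np.nan
    sigma_u: float = np.nan
    sigma_e: float = np.nan
    lrt_stat: float = np.nan
    p_asymptotic: float = np.nan
    p_wald: float = np.nan
    p_empirical: float = np.nan
    label: str = "ns"  # gain | loss | shared | ns
    na_reason: str = ""


class _PairedData:
    """Complete tumor/normal pairs with static design parts pre-rotated.

    Observation order inside each pair is (tumor, normal); the rotation maps
    pair rows to one "mean" row and one "difference" row each.
    """

    def __init__(self, y, G, s, covs, individual_ids):
        y = np.asarray(y, dtype=float)
        G = np.asarray(G, dtype=float)
        s = np.asarray(s, dtype=float)
        C = np.asarray(covs, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ids = np.asarray(individual_ids)
        if not (len(y) == len(G) == len(s) == len(C) == len(ids)):
            raise ValidationError("LMM inputs have inconsistent lengths")
        order_t, order_n = {}, {}
        for i, (ind, st) in enumerate(zip(ids, s)):
            (order_t if st == 1 else order_n)[ind] = i
        paired = [ind for ind in dict.fromkeys(ids)
                  if ind in order_t and ind in order_n]
        n_drop = len(set(ids)) - len(paired)
        if n_drop:
            logger.info("paired LMM: dropped %d unpaired individuals", n_drop)
        if len(paired) < 3:
            raise ValidationError("need at least 3 complete tumor/normal pairs")
        idx = np.array([[order_t[i], order_n[i]] for i in paired])
        self.n_pairs = len(paired)
        self.y = y[idx]          # (n_pairs, 2): tumor, normal
        self.G = G[idx[:, 0]]    # genotype is individual-level
        self.C = C[idx]          # (n_pairs, 2, k)
        if not np.allclose(G[idx[:, 0]], G[idx[:, 1]], equal_nan=True):
            raise ValidationError("genotype differs within an individual")
        self.mask = ~np.isnan(self.G)
        self.ym = (self.y[:, 0] + self.y[:, 1]) / _SQRT2
        self.yd = (self.y[:, 0] - self.y[:, 1]) / _SQRT2

    def designs(self, flip: np.ndarray | None = None):
        """Rotated full and reduced designs under an optional per-individual
        status relabeling (flip[i] True = individual i's labels swapped).

        Returns (Xm_full, Xd_full, Xm_red, Xd_red, gxs_col_index).
        """
        n, k = self.n_pairs, self.C.shape[2]
        if flip is None:
            flip = np.zeros(n, dtype=bool)
        # per-observation status after relabeling: tumor obs s = 1 - flip
        s_t = (~flip).astype(float)
        s_n = flip.astype(float)
        one_m = np.full(n, _SQRT2)
        zero = np.zeros(n)
        Gm = self.G * _SQRT2
        sm = (s_t + s_n) / _SQRT2          # = 1/sqrt(2), invariant
        sd = (s_t - s_n) / _SQRT2          # = +-1/sqrt(2)
        gsm = self.G * sm
        gsd = self.G * sd
        Cm = (self.C[:, 0, :] + self.C[:, 1, :]) / _SQRT2
        Cd = (self.C[:, 0, :] - self.C[:, 1, :]) / _SQRT2
        sCm = (s_t[:, None] * self.C[:, 0, :] + s_n[:, None] * self.C[:, 1, :]) / _SQRT2
        sCd = (s_t[:, None] * self.C[:, 0, :] - s_n[:, None] * self.C[:, 1, :]) / _SQRT2
        # column order: [1, G, s, G*s, C..., s*C...]
        Xm_full = np.column_stack([one_m, Gm, sm, gsm, Cm, sCm])
        Xd_full = np.column_stack([zero, zero, sd, gsd, Cd, sCd])
        red = [0, 1, 2] + list(range(4, 4 + 2 * k))
        return Xm_full, Xd_full, Xm_full[:, red], Xd_full[:, red], 3


def _fit_rotated(Xm, Xd, ym, yd, mask):
    """Concentrated-ML fit of the two-variance rotated model.

    Returns (loglik, beta, cov_beta, v_m, r).  ``mask`` drops pairs with a
    missing genotype (complete-case).
    """
    Xm, Xd, ym, yd = Xm[mask], Xd[mask], ym[mask], yd[mask]
    n = ym.size
    N = 2 * n
    Mm, Md = Xm.T @ Xm, Xd.T @ Xd
    bm, bd = Xm.T @ ym, Xd.T @ yd
    ymm, ydd = float(ym @ ym), float(yd @ yd)

    def profile(r):
        A = Mm + Md / r
        b = bm + bd / r
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        rss_m = ymm - 2.0 * beta @ bm + beta @ Mm @ beta
        rss_d = ydd - 2.0 * beta @ bd + beta @ Md @ beta
        q = max(rss_m + rss_d / r, 1e-300)
        v_m = q / N
        nll = 0.5 * (N * (np.log(2.0 * np.pi * v_m) + 1.0) + n * np.log(r))
        return nll, beta, v_m

    res = minimize_scalar(lambda t: profile(np.exp(t))[0],
                          bounds=(_LOG_R_MIN, 0.0), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [float(res.x), 0.0]  # check the sigma_u = 0 boundary exactly
    best = None
    for t in candidates:
        r = float(np.exp(t))
        nll, beta, v_m = profile(r)
        if beta is not None and (best is None or nll < best[0]):
            best = (nll, beta, v_m, r)
    if best is None:
        return None
    nll, beta, v_m, r = best
    A = Mm + Md / r
    cov_beta = v_m * np.linalg.inv(A)
    return -nll, beta, cov_beta, v_m, r


def fit_status_interaction_lmm(y, G, s, covs, individual_ids,
                               pair: CisPair | None = None) -> LmmResult:
    """Fit the full and reduced paired LMMs for one eQTL pair.

    ``covs`` enter both as main effects and as status x covariate
    interactions, matching the model formula.  The asymptotic p-value is the
    1-df LRT of the genotype x status term.
    """
    pair = pair or CisPair("", "", 0)
    try:
        data = _PairedData(y, G, s, covs, individual_ids)
    except ValidationError as e:
        return LmmResult(pair, na_reason=str(e))
    return _fit_pair(data, pair)


def _fit_pair(data: _PairedData, pair: CisPair) -> LmmResult:
    Xm, Xd, Xm_r, Xd_r, j = data.designs()
    X_full = np.vstack([Xm[data.mask], Xd[data.mask]])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        return LmmResult(pair, na_reason="rank-deficient design")
    full = _fit_rotated(Xm, Xd, data.ym, data.yd, data.mask)
    red = _fit_rotated(Xm_r, Xd_r, data.ym, data.yd, data.mask)
    if full is None or red is None:
        return LmmResult(pair, na_reason="singular fit")
    ll_f, beta, cov_beta, v_m, r = full
    ll_r = red[0]
    lrt = 2.0 * (ll_f - ll_r)
    se = float(np.sqrt(max(cov_beta[j, j], 0.0)))
    wald = (beta[j] / se) ** 2 if se > 0 else np.nan
    v_d = r * v_m
    return LmmResult(
        pair,
        beta_g=float(beta[1]), beta_status=float(beta[2]),
        beta_gxs=float(beta[j]), se_gxs=se,
        sigma_u=float(np.sqrt(max((v_m - v_d) / 2.0, 0.0))),
        sigma_e=float(np.sqrt(v_d)),
        lrt_stat=float(lrt),
        p_asymptotic=float(stats.chi2.sf(max(lrt, 0.0), 1)),
        p_wald=float(stats.chi2.sf(wald, 1)) if np.isfinite(wald) else np.nan,
    )


def _lrt_stat(data: _PairedData, flip: np.ndarray | None = None) -> float:
    Xm, Xd, Xm_r, Xd_r, _ = data.designs(flip)
    full = _fit_rotated(Xm, Xd, data.ym, data.yd, data.mask)
    red = _fit_rotated(Xm_r, Xd_r, data.ym, data.yd, data.mask)
    if full is None or red is None:
        return np.nan
    return 2.0 * (full[0] - red[0])


def permutation_pvalue(y, G, s, covs, individual_ids, B: int,
                       seed: int | np.random.Generator = 0) -> float:
    """Empirical p-value of the genotype x status LRT under within-individual
    status-label swaps: (1 + #{T_b >= T_obs}) / (1 + B)."""
    if B < 100:
        raise ConfigError("need at least 100 permutations")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    data = _PairedData(y, G, s, covs, individual_ids)
    t_obs = _lrt_stat(data)
    if not np.isfinite(t_obs):
        return np.nan
    count = 0
    for _ in range(B):
        flip = rng.random(data.n_pairs) < 0.5
        t_b = _lrt_stat(data, flip)
        if np.isfinite(t_b) and t_b >= t_obs - 1e-9:
            count += 1
    return (1 + count) / (1 + B)


def classify_gain_loss(tumor_top: list[CisPair], normal_top: list[CisPair],
                       lmm_results: list[LmmResult],
                       alpha: float = 0.05) -> list[LmmResult]:
    """Label condition-specific eQTLs.

    For pairs with empirical p < alpha: "gain" if the pair was significant
    in the tumor-context scan only, "loss" if in the normal-context scan
    only, "shared" if in both; "ns" otherwise.  A pair absent from both scan
    top lists violates the pipeline contract.
    """
    tum = {(p.variant_id, p.gene_id) for p in tumor_top}
    nor = {(p.variant_id, p.gene_id) for p in normal_top}
    for r in lmm_results:
        key = (r.pair.variant_id, r.pair.gene_id)
        if key not in tum and key not in nor:
            raise ValidationError(
                f"pair {key} present in neither scan's top-eQTL list")
        if r.na_reason or not np.isfinite(r.p_empirical) or r.p_empirical >= alpha:
            r.label = "ns"
        elif key in tum and key in nor:
            r.label = "shared"
        elif key in tum:
            r.label = "gain"
        else:
            r.label = "loss"
    return lmm_results


def run_condition_lmm(expr: ExpressionMatrix, geno: GenotypeMatrix,
                      fractions: CellFractionTable, sheet: SampleSheet,
                      pairs: list[CisPair], *, n_permutations: int = 1000,
                      n_pcs: int = 2, hidden: pd.DataFrame | None = None,
                      seed: int = 0) -> list[LmmResult]:
    """Fit the paired LMM (plus permutation p) for each top eQTL pair.

    Covariates: clinical binaries, epithelial fraction, ``n_pcs`` genotype
    PCs (default 2) and any supplied hidden factors; each also enters as a
    status interaction inside the fitter.
    """
    samples = [s for s in sheet.sample_ids if s in set(expr.sample_ids)]
    pcs = genotype_pcs(geno, n_pcs) if n_pcs else None
    covs = build_covariates(sheet, samples, pcs=pcs, hidden=hidden)
    covs = covs.copy()
    covs["epithelial_fraction"] = fractions.column("epithelial") \
        .reindex(samples).to_numpy()
    t = sheet.table.set_index("sample_id")
    ids = t.loc[samples, "individual_id"].to_numpy()
    status = t.loc[samples, "status"].to_numpy(dtype=float)
    sidx = expr.sample_index()
    Y = expr.log2p1()[:, [sidx[s] for s in samples]]
    gidx = expr.gene_index()
    vidx = geno.variant_index()
    g_rows = {ind: i for i, ind in enumerate(geno.individuals)}
    C = covs.to_numpy(dtype=float)

    ss = np.random.SeedSequence([seed, 6])
    child_seeds = ss.spawn(len(pairs))
    results = []
    for pair, child in zip(pairs, child_seeds):
        gi = gidx.get(pair.gene_id)
        vj = vidx.get(pair.variant_id)
        if gi is None or vj is None:
            results.append(LmmResult(pair, na_reason="missing gene or variant"))
            continue
        G = np.array([geno.dosages[g_rows[i], vj] for i in ids])
        res = fit_status_interaction_lmm(Y[gi], G, status, C, ids, pair=pair)
        if not res.na_reason:
            res.p_empirical = permutation_pvalue(
                Y[gi], G, status, C, ids, B=n_permutations,
                seed=np.random.default_rng(child))
        results.append(res)
    return results
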