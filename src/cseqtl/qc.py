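"""Germline variant QC: allele statistics, exact Hardy-Weinberg test, and
the joint variant filter (MAF, missingness, HWE, minor-allele carriers,
chromosome exclusion).

The HWE test is the exact conditional test: given the observed allele
counts, the probability of each attainable heterozygote count h is

    P(h) = multinomial(n; n_AA, h, n_aa) * 2**h / C(2n, n_minor)

and the two-sided p-value sums P over all h whose probability is at most
that of the observed table.  Weights are computed as exact integers
(multinomial coefficient times 2**h), so the "<= observed" comparison and
the final p-value carry no floating-point tie ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from .core import GenotypeMatrix, RunConfig, ValidationError, logger


@dataclass
class VariantQcReport:
    variant_id: str
    maf: float
    miss_rate: float
    hwe_p: float
    n_carriers: int
    passed: bool
    fail_reasons: tuple[str, ...]


def allele_stats(dosages) -> tuple[float, float, int]:
    """(minor allele frequency, missing rate, minor-allele carrier count).

    ``dosages`` are per-individual alt-allele counts with NaN for missing.
    An all-missing variant has undefined MAF (NaN) and zero carriers.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 1:
        raise ValueError("allele_stats expects a 1-D dosage vector")
    obs = d[~np.isnan(d)]
    if not np.isin(obs, (0.0, 1.0, 2.0)).all():
        raise ValidationError("dosage codes must be in {0,1,2} or missing")
    miss_rate = 1.0 - obs.size / d.size if d.size else 1.0
    if obs.size == 0:
        return float("nan"), miss_rate, 0
    p_alt = obs.sum() / (2 * obs.size)
    maf = min(p_alt, 1.0 - p_alt)
    if p_alt <= 0.5:  # minor allele is alt
        n_carriers = int((obs >= 1).sum())
    else:  # minor allele is ref
        n_carriers = int((obs <= 1).sum())
    return float(maf), float(miss_rate), n_carriers


def _hwe_weights(n: int, n_minor: int) -> tuple[np.ndarray, list[int]]:
    """Integer weights of every attainable heterozygote count.

    Returns (attainable h values, exact integer weights).  Weight(h) is
    multinomial(n; (n_major-h)/2 hom-major, h het, (n_minor-h)/2 hom-minor)
    times 2**h; the normaliser is their sum.
    """
    n_major = 2 * n - n_minor
    hs = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    weights = []
    for h in hs:
        n_aa = (n_minor - h) // 2
        # multinomial(n; n_AA, h, n_aa) = C(n, h) * C(n - h, n_aa)
        weights.append(comb(n, int(h)) * comb(n - int(h), n_aa) * (1 << int(h)))
    return hs, weights


def hwe_exact_pvalues(n: int, n_minor: int) -> dict[int, float]:
    """Exact two-sided HWE p-value for every attainable heterozygote count
    at fixed sample size ``n`` and minor-allele count ``n_minor``."""
    if n < 1:
        raise ValueError("need at least one genotype")
    if not 0 <= n_minor <= n:
        raise ValueError("n_minor must be in [0, n]")
    hs, weights = _hwe_weights(n, n_minor)
    total = sum(weights)
    order = sorted(range(len(weights)), key=weights.__getitem__)
    cum = 0
    pvals = {}
    i = 0
    while i < len(order):
        # group exact ties so every tied configuration gets the same p
        j = i
        w = weights[order[i]]
        while j < len(order) and weights[order[j]] == w:
            cum += weights[order[j]]
            j += 1
        p = float(Fraction(cum, total))
        for k in range(i, j):
            pvals[int(hs[order[k]])] = p
        i = j
    return pvals


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one genotype table."""
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    return hwe_exact_pvalues(n, n_minor)[n_Aa]


def filter_variants(geno: GenotypeMatrix,
                    cfg: RunConfig) -> tuple[GenotypeMatrix, list[VariantQcReport]]:
    """Apply all variant filters jointly and report per-variant reasons.

    A variant passes iff maf >= maf_min, miss_rate <= miss_max,
    hwe_p >= hwe_p_min, n_carriers >= min_carriers and its chromosome is not
    excluded (chrY by default).
    """
    if geno.n_variants == 0 or geno.n_individuals == 0:
        raise ValidationError("cannot QC an empty genotype matrix")
    drop = {c for c in cfg.drop_chroms}
    reports: list[VariantQcReport] = []
    keep = np.zeros(geno.n_variants, dtype=bool)
    for j, v in enumerate(geno.variants):
        d = geno.dosages[:, j]
        maf, miss_rate, n_carriers = allele_stats(d)
        obs = d[~np.isnan(d)]
        if obs.size:
            counts = [(obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()]
            hwe_p = hwe_exact_test(*map(int, counts))
        else:
            hwe_p = float("nan")
        reasons = []
        if np.isnan(maf):
            reasons.append("missing")
        else:
            if maf < cfg.maf_min:
                reasons.append("maf")
            if miss_rate > cfg.miss_max:
                reasons.append("missing")
            if hwe_p < cfg.hwe_p_min:
                reasons.append("hwe")
            if n_carriers < cfg.min_carriers:
                reasons.append("carriers")
        if v.chrom in drop:
            reasons.append("chromY" if v.chrom == "chrY" else "chrom")
        passed = not reasons
        keep[j] = passed
        reports.append(VariantQcReport(v.id, maf, miss_rate, hwe_p,
                                       n_carriers, passed, tuple(reasons)))
    logger.info("filter_variants: %d/%d variants pass", int(keep.sum()),
                geno.n_variants)
    return geno.subset_variants(keep), reports
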