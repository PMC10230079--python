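"""Approximate-Bayes-factor colocalization (PP0-PP4) and single-causal
fine-mapping (PIP, credible sets).

For one variant with effect estimate beta and standard error se, the
approximate Bayes factor of association against the null under a N(0, W)
effect prior is

    log ABF = 1/2 [ log(1 - r) + r z^2 ],   r = W / (V + W),  z = beta/se,
    V = se^2.

Colocalization of two traits over a shared m-variant region assumes at most
one causal variant per trait and compares five hypotheses: H0 no
association, H1/H2 association with one trait only, H3 two distinct causal
variants, H4 one shared causal variant.  All sums are taken in log space.

Fine-mapping uses the single-causal model with a uniform prior over which
variant is causal: PIP_i = softmax(log ABF)_i, and the credible set is the
smallest PIP-descending prefix whose cumulative PIP reaches the level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .core import ValidationError

# conventional prior effect SDs: 0.15 for quantitative, 0.2 for binary traits
W_QUANTITATIVE = 0.15 ** 2
W_BINARY = 0.2 ** 2

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    priors: tuple[float, float, float]

    def __post_init__(self):
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-10:
            raise ValidationError("colocalization posteriors do not sum to 1")


@dataclass
class FineMapResult:
    variant_ids: list[str]
    pip: np.ndarray
    credible_set: list[str]
    credible_level: float


def wakefield_abf(beta, se, W: float = W_QUANTITATIVE):
    """log approximate Bayes factor of association vs the null (vectorised)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be positive")
    if W <= 0:
        raise ValidationError("prior variance W must be positive")
    V = se ** 2
    r = W / (V + W)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return float(out) if out.ndim == 0 else out


def pvalue_to_abf_inputs(p, maf, n, case_fraction: float | None = None):
    """(beta proxy, se proxy) from p / MAF / sample size summary statistics.

    z is recovered sign-free from the two-sided p (the ABF depends on z only
    through z^2); se = 1 / sqrt(2 maf (1-maf) n), scaled by
    1/sqrt(case_fraction (1-case_fraction)) for binary traits.
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError(
            "p must be in (0, 1]; replace p = 0 with the smallest "
            "representable float")
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValidationError("maf must be in (0, 0.5]")
    if np.any(n <= 1):
        raise ValidationError("n must exceed 1")
    z = stats.norm.isf(p / 2.0)
    denom = 2.0 * maf * (1.0 - maf) * n
    if case_fraction is not None:
        if not 0 < case_fraction < 1:
            raise ValidationError("case_fraction must be in (0, 1)")
        denom = denom * case_fraction * (1.0 - case_fraction)
    se = 1.0 / np.sqrt(denom)
    return z * se, se


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_pp(abf1, abf2, p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
             p12: float = DEFAULT_P12) -> ColocResult:
    """Five-hypothesis colocalization posterior from per-variant log ABFs."""
    a1 = np.asarray(abf1, dtype=float)
    a2 = np.asarray(abf2, dtype=float)
    if a1.size == 0:
        raise ValidationError("need at least one variant")
    if a1.shape != a2.shape:
        raise ValidationError("trait ABF vectors differ in length")
    for name, v in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0 < v < 1:
            raise ValidationError(f"{name} must be in (0, 1)")
    L1 = logsumexp(a1)
    L2 = logsumexp(a2)
    L12 = logsumexp(a1 + a2)
    # sum over i != j of exp(a1_i + a2_j) = S1*S2 - sum_i exp(a1_i + a2_i)
    L3 = _log_diff_exp(L1 + L2, L12)
    logs = np.array([
        0.0,
        np.log(p1) + L1,
        np.log(p2) + L2,
        np.log(p1) + np.log(p2) + L3,
        np.log(p12) + L12,
    ])
    pp = np.exp(logs - logsumexp(logs))
    pp = pp / pp.sum()
    return ColocResult(*map(float, pp), n_variants=int(a1.size),
                       priors=(p1, p2, p12))


def finemap_pip(abfs, variant_ids=None, level: float = 0.99) -> FineMapResult:
    """PIPs under the single-causal, uniform-prior model and the smallest
    credible set at ``level`` (ties in PIP broken by variant id)."""
    a = np.asarray(abfs, dtype=float)
    if a.size == 0:
        raise ValidationError("need at least one variant")
    if not 0 < level < 1:
        raise ValidationError("credible level must be in (0, 1)")
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(a.size)]
    if len(variant_ids) != a.size:
        raise ValidationError("variant_ids length mismatch")
    pip = np.exp(a - logsumexp(a))
    pip = pip / pip.sum()
    order = sorted(range(a.size), key=lambda i: (-pip[i], str(variant_ids[i])))
    cum = 0.0
    cs = []
    for i in order:
        cs.append(str(variant_ids[i]))
        cum += pip[i]
        if cum >= level - 1e-12:
            break
    return FineMapResult(list(map(str, variant_ids)), pip, cs, level)


def simulate_region_zscores(m: int, causal_idx: int, z_causal: float,
                            r2: float, rng: np.random.Generator) -> np.ndarray:
    """Marginal z-scores for an m-variant region with one causal variant.

    Variants share an equicorrelated LD block with the causal variant
    (pairwise genotype correlation sqrt(r2)); under the standard
    summary-statistic model, z ~ MVN(R e_c z_causal, R) with R the LD
    matrix.  Used by the coverage and colocalization simulations.
    """
    if not 0 <= r2 < 1:
        raise ValidationError("r2 must be in [0, 1)")
    rho = np.sqrt(r2)
    R = np.full((m, m), rho * rho)
    np.fill_diagonal(R, 1.0)
    R[causal_idx, :] = rho
    R[:, causal_idx] = rho
    R[causal_idx, causal_idx] = 1.0
    mean = R[:, causal_idx] * z_causal
    L = np.linalg.cholesky(R)
    return mean + L @ rng.standard_normal(m)
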