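"""Cell-fraction handling: validation/renormalisation of externally supplied
fraction tables and a transparent reference-based non-negative deconvolution.

The deconvolution solves, per bulk sample, a non-negative least-squares fit
of the bulk TPM profile on the signature-matrix columns over the shared
genes, then renormalises the coefficients to proportions.  It is a simple,
fully reproducible estimator of the epithelial/immune/stromal mix; the
pipeline equally accepts a precomputed fraction table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .core import (
    CellFractionTable,
    ExpressionMatrix,
    ValidationError,
    logger,
)


@dataclass
class SignatureMatrix:
    """Mean expression per cell type over signature genes."""

    gene_ids: list[str]
    cell_types: list[str]
    values: np.ndarray  # genes x cell types, non-negative

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValidationError("signature matrix shape mismatch")
        if (self.values < 0).any():
            raise ValidationError("signature matrix must be non-negative")
        if len(self.cell_types) < 2:
            raise ValidationError("signature matrix needs >= 2 cell types")


def renormalize_fractions(sample_ids, cell_types, raw) -> CellFractionTable:
    """Divide each row of a non-negative samples x types matrix by its sum."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValidationError("raw fractions must be non-negative")
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        bad = sample_ids[int(np.argmax(sums <= 0))]
        raise ValidationError(f"sample {bad}: all-zero fraction row")
    return CellFractionTable(list(sample_ids), list(cell_types),
                             raw / sums[:, None])


def nnls_deconvolve(bulk: ExpressionMatrix,
                    sig: SignatureMatrix) -> CellFractionTable:
    """Estimate cell-type proportions per bulk sample by NNLS on the
    signature matrix; coefficients are renormalised to sum to one.

    A sample whose NNLS solution is all-zero (bulk orthogonal to every
    signature) gets uniform fractions, with a warning.
    """
    shared = [g for g in sig.gene_ids if g in set(bulk.gene_ids)]
    if len(shared) < 10:
        raise ValidationError(
            f"only {len(shared)} genes shared between bulk and signature "
            "(need >= 10)")
    bidx = bulk.gene_index()
    sidx = {g: i for i, g in enumerate(sig.gene_ids)}
    A = sig.values[[sidx[g] for g in shared], :]
    B = bulk.values[[bidx[g] for g in shared], :]
    raw = np.zeros((len(bulk.sample_ids), len(sig.cell_types)))
    for j in range(B.shape[1]):
        coef, _ = nnls(A, B[:, j])
        if coef.sum() <= 0:
            warnings.warn(
                f"sample {bulk.sample_ids[j]}: all-zero NNLS solution; "
                "assigning uniform fractions", RuntimeWarning)
            logger.warning("nnls_deconvolve: degenerate sample %s",
                           bulk.sample_ids[j])
            coef = np.ones(len(sig.cell_types))
        raw[j] = coef
    return renormalize_fractions(bulk.sample_ids, sig.cell_types, raw)
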