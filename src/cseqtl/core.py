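"""Shared domain types and run configuration.

All genomic positions are 1-based inclusive (VCF convention).  Genotypes are
additive alt-allele dosages in {0, 1, 2}; missing calls are stored as NaN in
float arrays so that vectorised complete-case handling stays cheap.
Chromosome names are normalised to the "chr"-prefixed dialect on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger("cseqtl")

KNOWN_BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class ConfigError(ValueError):
    """An invalid configuration value."""


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    return name if name.startswith("chr") else "chr" + name


@dataclass(frozen=True)
class VariantRecord:
    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1")
        if self.alt == self.ref:
            raise ValidationError(f"variant {self.id}: alt equals ref")


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix (NaN = missing call)."""

    individuals: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray  # float, shape (n_individuals, n_variants)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("dosage entries must be in {0,1,2} or missing")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).loc[lambda s: s.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id: {dup}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[str, int]:
        return {v.id: j for j, v in enumerate(self.variants)}

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            variants=[self.variants[j] for j in keep],
            dosages=self.dosages[:, keep].copy(),
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str  # "+" or "-"
    biotype: str = "other"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.biotype not in KNOWN_BIOTYPES:
            object.__setattr__(self, "biotype", "other")


@dataclass
class SampleSheet:
    """Per-sample metadata: identity, disease status and clinical covariates.

    ``status`` encodes tumor = 1 and normal = 0.  Each individual may
    contribute at most one sample per status.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "individual_id", "status")
    OPTIONAL = ("age_group", "sex", "smoking", "drinking",
                "tnm_stage", "surv_time", "surv_event")

    def __post_init__(self):
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        if not t["status"].isin((0, 1)).all():
            raise ValidationError("status must be 0 (normal) or 1 (tumor)")
        dup = t.duplicated(subset=["individual_id", "status"])
        if dup.any():
            bad = t.loc[dup, "individual_id"].iloc[0]
            raise ValidationError(
                f"individual {bad} has more than one sample with the same status"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for_status(self, status: int) -> list[str]:
        t = self.table
        return list(t.loc[t["status"] == status, "sample_id"])

    def paired_individuals(self) -> list[str]:
        """Individuals contributing both a tumor and a normal sample."""
        counts = self.table.groupby("individual_id")["status"].nunique()
        return sorted(counts[counts == 2].index)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # non-negative TPM

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("expression shape mismatch")
        if np.isnan(self.values).any():
            raise ValidationError("expression contains NaN")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative TPM at gene {self.gene_ids[i]}, sample {self.sample_ids[j]}"
            )

    def log2p1(self) -> np.ndarray:
        """log2(TPM + 1), the scale on which all models operate."""
        return np.log2(self.values + 1.0)

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class CellFractionTable:
    """Per-sample cell-type proportions; rows are non-negative and sum to 1."""

    sample_ids: list[str]
    cell_types: list[str]
    fractions: np.ndarray  # samples x types

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValidationError("fraction table shape mismatch")
        if (self.fractions < 0).any():
            raise ValidationError("fractions must be non-negative")
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValidationError(f"fractions for sample {bad} do not sum to 1")

    def column(self, cell_type: str) -> pd.Series:
        j = self.cell_types.index(cell_type)
        return pd.Series(self.fractions[:, j], index=self.sample_ids, name=cell_type)


@dataclass
class RunConfig:
    """Pipeline thresholds and window sizes.

    Defaults follow standard cis-eQTL practice: MAF >= 1%, missingness <= 5%,
    Hardy-Weinberg exact p >= 1e-6, minor allele carried by >= 10 individuals,
    a +/-1 Mb cis window, stage-1 adjusted p <= 0.01, stage-2 empirical
    p < 0.05 with >= 100 permutations, and the conventional colocalization
    priors p1 = p2 = 1e-4, p12 = 1e-5.
    """

    cis_window_bp: int = 1_000_000
    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_p_min: float = 1e-6
    min_carriers: int = 10
    drop_chroms: tuple[str, ...] = ("chrY",)
    stage1_alpha: float = 0.01
    stage2_alpha: float = 0.05
    n_permutations: int = 1000
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    promoter_window_bp: int = 2_000
    seed: int = 0

    def __post_init__(self):
        for name in ("maf_min", "miss_max", "hwe_p_min", "stage1_alpha",
                     "stage2_alpha", "p1", "p2", "p12"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.maf_min > 0.5:
            raise ConfigError("maf_min cannot exceed 0.5")
        if self.cis_window_bp <= 0 or self.promoter_window_bp <= 0:
            raise ConfigError("window sizes must be positive")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if self.min_carriers < 0:
            raise ConfigError("min_carriers must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "drop_chroms" in d:
            d = dict(d)
            d["drop_chroms"] = tuple(normalize_chrom(c) for c in d["drop_chroms"])
        return cls(**d)
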