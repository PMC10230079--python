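"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through cyvcf2; everything tabular is plain TSV via pandas.
Readers never mutate their inputs and are deterministic.  Multi-allelic VCF
records are skipped (with a logged count) because the pipeline models
biallelic additive dosages only.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import (
    CellFractionTable,
    ExpressionMatrix,
    FormatError,
    GeneAnnotation,
    GenotypeMatrix,
    RunConfig,
    SampleSheet,
    ValidationError,
    VariantRecord,
    logger,
    normalize_chrom,
)


def read_genotypes(vcf_path, exclude_chroms=None) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix.

    Dosage is the alt-allele count from GT.  "./." and half-calls map to
    missing.  Multi-allelic records are skipped and counted; variants on
    ``exclude_chroms`` (normalised names, e.g. {"chrY"}) are dropped.
    """
    exclude = {normalize_chrom(c) for c in (exclude_chroms or ())}
    vcf_path = os.fspath(vcf_path)
    vcf = VCF(vcf_path, gts012=False)
    individuals = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    n_excluded = 0
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom = normalize_chrom(rec.CHROM)
        if chrom in exclude:
            n_excluded += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{chrom}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if vid in seen:
            raise ValidationError(f"duplicate variant id: {vid}")
        seen.add(vid)
        # gt_types uses 2 for "unknown"; decode from genotypes for half-calls
        dos = np.full(len(individuals), np.nan)
        for i, g in enumerate(rec.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if len(alleles) != 2:  # ./., half-calls, haploid
                continue
            dos[i] = float(sum(1 for a in alleles if a == 1))
        variants.append(VariantRecord(vid, chrom, rec.POS, rec.REF, rec.ALT[0]))
        rows.append(dos)
    vcf.close()
    if variants and not individuals:
        raise FormatError(f"{vcf_path}: no GT sample columns in VCF")
    if n_multi:
        logger.info("read_genotypes: skipped %d multi-allelic records", n_multi)
    if n_excluded:
        logger.info("read_genotypes: dropped %d records on excluded chromosomes",
                    n_excluded)
    dosages = (np.array(rows).T if rows
               else np.empty((len(individuals), 0)))
    return GenotypeMatrix(individuals, variants, dosages)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal uncompressed VCF v4.2 with GT only (round-trips
    through :func:`read_genotypes`)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({v.chrom for v in geno.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individuals) + "\n")
        order = np.lexsort(([v.pos for v in geno.variants],
                            [v.chrom for v in geno.variants]))
        for j in order:
            v = geno.variants[j]
            gts = "\t".join(
                "./." if np.isnan(d) else code[d] for d in geno.dosages[:, j]
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_expression(tsv_path) -> ExpressionMatrix:
    """Read a genes x samples TPM table (first column = gene ids)."""
    try:
        df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as e:
        raise FormatError(f"{tsv_path}: empty expression file") from e
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"{tsv_path}: expression table has no data")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{tsv_path}: non-numeric or missing value at gene "
            f"{df.index[i]}, sample {df.columns[j]}")
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)), values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids) \
        .rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a BED-like gene table (gene_id, chrom, tss, tes, strand, biotype).

    TSS must already be strand-resolved by the producer (for "-" strand genes
    it is the larger coordinate); no strand arithmetic is done here.
    Unknown biotypes map to "other".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "chrom", "tss", "tes", "strand", "biotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id: {dup}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(GeneAnnotation(
            gene_id=row.gene_id,
            chrom=normalize_chrom(row.chrom),
            tss=int(row.tss),
            tes=int(row.tes),
            strand=row.strand,
            biotype=row.biotype,
        ))
    return genes


def write_annotation(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame([dataclasses.asdict(g) for g in genes]).to_csv(
        path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    if "individual_id" in df.columns:
        df["individual_id"] = df["individual_id"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_fractions(path) -> CellFractionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellFractionTable(list(df.index.astype(str)),
                            list(df.columns.astype(str)),
                            df.to_numpy(dtype=float))


def write_fractions(tab: CellFractionTable, path) -> None:
    pd.DataFrame(tab.fractions, index=tab.sample_ids, columns=tab.cell_types) \
        .rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")


def records_to_frame(records) -> pd.DataFrame:
    """Flatten a homogeneous list of result dataclasses into a DataFrame.

    Nested dataclass fields (e.g. a CisPair inside a result) are expanded
    with dotted column names.
    """
    if not records:
        return pd.DataFrame()
    rows = []
    for r in records:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        flat = {}
        for k, v in d.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    flat[f"{k}.{k2}"] = v2
            else:
                flat[k] = v
        rows.append(flat)
    return pd.DataFrame(rows)


def write_results_table(records, path) -> None:
    """Write any homogeneous result-record list as a TSV (header + one row
    per record, input order, floats at >= 6 significant digits)."""
    df = records_to_frame(records)
    if df.empty and records == []:
        # header-only file needs at least column names; none known -> empty header
        Path(path).write_text("\n")
        return
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise FormatError(f"{path}: config must be a flat mapping")
    return RunConfig.from_dict(d)


def read_summary_stats(path) -> pd.DataFrame:
    """Read GWAS/eQTL summary statistics (variant_id plus beta/se or
    p/maf/n columns)."""
    df = pd.read_csv(path, sep="\t")
    if "variant_id" not in df.columns:
        raise FormatError(f"{path}: summary stats need a variant_id column")
    has_bse = {"beta", "se"} <= set(df.columns)
    has_p = {"p", "maf", "n"} <= set(df.columns)
    if not (has_bse or has_p):
        raise FormatError(f"{path}: need beta+se or p+maf+n columns")
    if has_bse and (df["se"] <= 0).any():
        raise ValidationError(f"{path}: se must be positive")
    if df["variant_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate variant ids")
    return df
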