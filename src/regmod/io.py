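"""File-format boundary: VCF, tab-separated tables, locus lists, configs.

All file coordinates are 1-based inclusive (VCF convention); intervals are
converted to the internal 0-based half-open representation exactly once,
here.  Every written file carries the generating seed in a header comment
when one is supplied.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, ExpressionMatrix, GenomicInterval, GenotypeMatrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)
_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


class FileFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF


def write_vcf(geno: GenotypeMatrix, path, seed: int | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(VCF_HEADER)
        contigs = geno.variants["chrom"].astype(str).unique()
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        if seed is not None:
            fh.write(f"##regmod_seed={seed}\n")
        cols = "\t".join(geno.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            gts = "\t".join(_GT_CODES[int(d)] for d in geno.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (cyvcf2; gts012 coding)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, alt, 0.0))
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # cyvcf2 codes unknown as 3 under gts012
        dosage_cols.append(gt)
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "maf"]
    )
    geno = GenotypeMatrix(samples, variants, np.column_stack(dosage_cols))
    geno.variants["maf"] = geno.maf_from_dosages()
    return geno


# ---------------------------------------------------------------------------
# tab-separated tables


def _write_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    with Path(path).open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df


def write_dosage_tsv(geno: GenotypeMatrix, path, seed: int | None = None) -> None:
    """One row per variant: annotation columns then one column per sample."""
    meta = geno.variants.copy()
    mat = pd.DataFrame(geno.dosages.T, columns=geno.sample_ids)
    _write_tsv(pd.concat([meta, mat], axis=1), path, seed)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = _read_tsv(path)
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=np.int8).T
    geno = GenotypeMatrix(sample_ids, df[meta_cols].reset_index(drop=True), dosages)
    geno.variants["maf"] = geno.maf_from_dosages()
    return geno


def write_expression_tsv(expr: ExpressionMatrix, path, seed: int | None = None) -> None:
    mat = pd.DataFrame(expr.values.T, columns=expr.sample_ids)
    _write_tsv(pd.concat([expr.probes.reset_index(drop=True), mat], axis=1), path, seed)


def read_expression_tsv(path, tissue: str) -> ExpressionMatrix:
    df = _read_tsv(path)
    meta_cols = ["probe_id", "gene", "chrom", "pos"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    return ExpressionMatrix(
        sample_ids, df[meta_cols].reset_index(drop=True), tissue,
        df[sample_ids].to_numpy(dtype=float).T,
    )


def write_pattern_tsv(pattern, path, seed: int | None = None) -> None:
    df = pattern.variants.copy()
    df["neg_log10_p"] = pattern.neg_log10_p
    df["sign"] = pattern.sign
    _write_tsv(df, path, seed)


def read_pattern_tsv(path, trait: str, anchor: tuple[str, int]):
    from .theta import AssociationPattern

    df = _read_tsv(path)
    return AssociationPattern(
        trait=trait,
        variants=df[["variant_id", "chrom", "pos", "ref", "alt", "maf"]].copy(),
        neg_log10_p=df["neg_log10_p"].to_numpy(float),
        sign=df["sign"].to_numpy(float),
        anchor=anchor,
    )


# ---------------------------------------------------------------------------
# risk-locus lists


def parse_locus_mb(chrom: str, begin_mb: float, end_mb: float, name: str = "") -> GenomicInterval:
    """A locus printed in megabases (e.g. chr2: 102.8-103.3) to base pairs,
    1-based inclusive at the boundary, internal 0-based half-open."""
    start1 = int(round(begin_mb * 1e6)) + 1
    end1 = int(round(end_mb * 1e6))
    return GenomicInterval.from_1based(str(chrom), start1, end1, name)


def read_locus_tsv(path) -> list[GenomicInterval]:
    """BED-like TSV with 1-based inclusive start/end columns
    (name, chrom, start, end)."""
    df = _read_tsv(path)
    required = {"name", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise FileFormatError(f"{path}: expected columns {sorted(required)}")
    out = []
    for k, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end), str(row.name))
            )
        except (TypeError, ValueError) as exc:
            raise FileFormatError(f"{path}: bad row {k + 2}: {exc}") from exc
    return out


def write_locus_tsv(loci: list[GenomicInterval], path, seed: int | None = None) -> None:
    rows = [(iv.name, *iv.to_1based()) for iv in loci]
    _write_tsv(pd.DataFrame(rows, columns=["name", "chrom", "start", "end"]), path, seed)


# ---------------------------------------------------------------------------
# theta comparison tables


def write_theta_tsv(comparisons, path, seed: int | None = None) -> None:
    rows = [
        (c.trait_a, c.trait_b, c.r_w, c.r_ws, c.theta, c.n_informative, c.defined)
        for c in comparisons
    ]
    _write_tsv(
        pd.DataFrame(
            rows, columns=["a", "b", "r_w", "r_ws", "theta", "n_informative", "defined"]
        ),
        path,
        seed,
    )
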