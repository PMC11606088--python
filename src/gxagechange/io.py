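"""File formats: dosage matrices (TSV and VCF), phenotype tables.

The dosage TSV is wide: one row per variant with metadata columns
(variant, chrom, pos, ea, oa) followed by one dosage column per sample id;
dosages are on the 0-2 effect-allele scale. VCF input is read with cyvcf2,
preferring a DS (dosage) FORMAT field and falling back to allele counts from
GT. VCF output is minimal VCF 4.2 text with a DS FORMAT field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_genotypes",
    "read_phenotypes",
]

META_COLS = ["variant", "chrom", "pos", "ea", "oa"]


def _validate(dosages: np.ndarray, source: str) -> None:
    if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
        raise ValueError(f"{source}: dosages outside [0, 2]")


def read_dosage_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a wide dosage TSV.

    Returns (dosages shaped samples x variants, variant metadata, sample
    ids). Malformed numeric fields raise with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    sample_ids = [c for c in df.columns if c not in META_COLS]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    try:
        dosages = df[sample_ids].to_numpy(dtype=float).T
    except ValueError as err:
        for i, (_, row) in enumerate(df[sample_ids].iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any() and not row.isna().any():
                raise ValueError(f"{path}: malformed dosage on line {i}") from err
        raise
    _validate(dosages, str(path))
    meta = df[META_COLS].copy()
    meta["pos"] = meta["pos"].astype(int)
    meta["eaf"] = np.nanmean(dosages, axis=0) / 2.0
    return dosages, meta, sample_ids


def write_dosage_tsv(
    path: str | Path, dosages: np.ndarray, variants: pd.DataFrame, sample_ids: list
) -> None:
    mat = np.asarray(dosages, dtype=float)
    _validate(mat, str(path))
    body = pd.DataFrame(np.round(mat.T, 4), columns=[str(s) for s in sample_ids])
    out = pd.concat([variants[META_COLS].reset_index(drop=True), body], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read dosages from a VCF, using DS when present, else GT allele counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: multi-allelic record at {var.CHROM}:{var.POS}")
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError):
            gts = np.asarray(var.genotype.array())[:, :2]
            if np.any(gts < 0):
                raise ValueError(f"{path}: missing GT at {var.CHROM}:{var.POS}")
            ds = gts.sum(axis=1).astype(float)
        rows.append(ds)
        meta.append(
            {
                "variant": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ea": var.ALT[0],
                "oa": var.REF,
            }
        )
    dosages = np.asarray(rows, dtype=float).T
    _validate(dosages, str(path))
    variants = pd.DataFrame(meta)
    variants["eaf"] = np.nanmean(dosages, axis=0) / 2.0
    return dosages, variants, sample_ids


def write_vcf(
    path: str | Path, dosages: np.ndarray, variants: pd.DataFrame, sample_ids: list
) -> None:
    """Write a minimal VCF 4.2 with dosages in a DS FORMAT field.

    The effect allele is written as ALT so that DS counts effect alleles.
    """
    mat = np.asarray(dosages, dtype=float)
    _validate(mat, str(path))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        for chrom in pd.unique(variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(str(s) for s in sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        order = np.argsort(
            variants["pos"].to_numpy(), kind="mergesort"
        )  # position-sorted within input chrom order
        for j in order:
            v = variants.iloc[j]
            ds = "\t".join(f"{d:.4f}" for d in mat[:, j])
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['variant']}\t{v['oa']}\t{v['ea']}"
                f"\t.\t.\t.\tDS\t{ds}\n"
            )


def read_genotypes(path: str | Path, fmt: str | None = None):
    """Dispatch on format: ``dosage`` TSV or ``vcf`` (by extension if None)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz") else "dosage"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with at least an ``id`` column."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError(f"{path}: phenotype table must carry an 'id' column")
    return df
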