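"""Readers and writers for genotype and phenotype files.

VCF parsing goes through cyvcf2; only the GT field is used
(0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing) and dosage columns are
re-oriented to the minor allele from the sample frequency.  PLINK
bed/bim/fam is read with a small built-in codec for the SNP-major
2-bit layout.  Phenotypes are tab/comma-separated tables with a header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, fold_to_minor
from .windows import Region

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- VCF

def read_vcf(path, region: Region | None = None,
             skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Load biallelic SNVs from a VCF as minor-allele dosages.

    Multiallelic records are skipped (or an error raised with
    ``skip_multiallelic=False``); sample order follows the file.  With a
    ``region``, only variants with POS in ``[start, end]`` on the
    region's chromosome are kept.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples)
    positions: list[int] = []
    cols: list[np.ndarray] = []
    chrom = region.chrom if region is not None else None
    for v in vcf:
        if region is not None and (
            v.CHROM != region.chrom or not region.start <= v.POS <= region.end
        ):
            continue
        if len(v.ALT) != 1:
            if skip_multiallelic:
                logger.info("skipping multiallelic record at %s:%d", v.CHROM, v.POS)
                continue
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}")
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError(
                "VCF spans multiple chromosomes; pass a region to select one"
            )
        if positions and v.POS <= positions[-1]:
            raise ValueError(f"VCF not position-sorted at {v.CHROM}:{v.POS}")
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        positions.append(v.POS)
        cols.append(g)
    vcf.close()
    if not positions:
        raise ValueError("no biallelic variants found in the requested region")
    dosages = fold_to_minor(np.column_stack(cols))
    return GenotypeMatrix(samples, np.array(positions), dosages, chrom=chrom or "1")


def write_vcf(path, genotypes: GenotypeMatrix) -> None:
    """Write dosages as a minimal GT-only VCF (A/C placeholder alleles)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genotypes.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.sample_ids))
            + "\n"
        )
        for j, pos in enumerate(genotypes.positions):
            gts = "\t".join(gt_map[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"{genotypes.chrom}\t{pos}\tv{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------- PLINK

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit PLINK codes -> dosage of the A1 allele:
# 00 hom A1 -> 2, 01 missing, 10 het -> 1, 11 hom A2 -> 0
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix, region: Region | None = None) -> GenotypeMatrix:
    """Load a PLINK bed/bim/fam fileset as minor-allele dosages.

    ``prefix`` names the fileset without extension.  The SNP-major .bed
    layout is decoded directly; the A1 dosage is folded to the minor
    allele from the sample frequency.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    n = len(fam)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    bytes_per_var = (n + 3) // 4
    body = raw[3:].reshape(len(bim), bytes_per_var)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((len(bim), bytes_per_var * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # samples x variants

    keep = np.ones(len(bim), dtype=bool)
    chrom = region.chrom if region is not None else str(bim["chrom"].iloc[0])
    if region is not None:
        keep = (
            (bim["chrom"].astype(str) == region.chrom)
            & (bim["pos"] >= region.start)
            & (bim["pos"] <= region.end)
        ).to_numpy()
        if not keep.any():
            raise ValueError("no variants found in the requested region")
    positions = bim["pos"].to_numpy()[keep]
    order = np.argsort(positions, kind="stable")
    dosages = fold_to_minor(dosages[:, keep][:, order])
    return GenotypeMatrix(
        fam["iid"].to_numpy(), positions[order], dosages, chrom=chrom
    )


def write_plink(prefix, genotypes: GenotypeMatrix) -> None:
    """Write a bed/bim/fam fileset (A1 = minor placeholder C, A2 = A)."""
    prefix = Path(prefix)
    n = genotypes.n_samples
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in genotypes.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, pos in enumerate(genotypes.positions):
            fh.write(f"{genotypes.chrom}\tv{j}\t0\t{pos}\tC\tA\n")
    bytes_per_var = (n + 3) // 4
    out = np.zeros((genotypes.n_variants, bytes_per_var), dtype=np.uint8)
    for j in range(genotypes.n_variants):
        for i, d in enumerate(genotypes.dosages[:, j]):
            out[j, i // 4] |= _DOSAGE_TO_CODE[int(d)] << (2 * (i % 4))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        out.tofile(fh)


def read_genotypes(path, fmt: str | None = None,
                   region: Region | None = None) -> GenotypeMatrix:
    """Dispatch to the VCF or PLINK reader.

    ``fmt`` is ``"vcf"`` or ``"plink-bed"``; when omitted it is guessed
    from the file name.
    """
    p = str(path)
    if fmt is None:
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "plink-bed"
    if fmt == "vcf":
        return read_vcf(p, region)
    if fmt == "plink-bed":
        prefix = p[:-4] if p.endswith(".bed") else p
        return read_plink(prefix, region)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ------------------------------------------------------------ phenotype

def read_phenotype(
    path,
    id_column: str = "sample_id",
    value_column: str = "value",
    transform: str | None = None,
) -> pd.Series:
    """Read a phenotype table into a Series indexed by sample id.

    ``transform`` is ``None``, ``"log"`` (natural) or ``"log10"``;
    non-positive values under a log transform raise an error naming the
    offending sample.  Duplicate ids and non-numeric values are
    rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (id_column, value_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in phenotype file")
    values = pd.to_numeric(df[value_column], errors="coerce")
    if values.isna().any() and df[value_column].notna().any():
        bad = ids[values.isna() & df[value_column].notna()]
        if len(bad):
            raise ValueError(f"non-numeric phenotype for sample {bad.iloc[0]!r}")
    if not np.isfinite(values.dropna()).all():
        raise ValueError("non-finite phenotype values present")
    if transform in ("log", "log10"):
        if (values <= 0).any():
            bad = ids[values <= 0].iloc[0]
            raise ValueError(
                f"cannot log-transform non-positive phenotype of sample {bad!r}"
            )
        values = np.log(values) if transform == "log" else np.log10(values)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    return pd.Series(values.to_numpy(float), index=pd.Index(ids, name=id_column),
                     name=value_column)


def write_phenotype(path, y: np.ndarray, sample_ids) -> None:
    """Write a two-column TSV (sample_id, value)."""
    pd.DataFrame({"sample_id": sample_ids, "value": y}).to_csv(
        path, sep="\t", index=False
    )
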