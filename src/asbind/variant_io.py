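"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based, half-open everywhere; the only conversion
happens at the VCF boundary (VCF POS is 1-based).  Tabular inputs are
tab-delimited with a header line; lines starting with ``#`` are comments.
Allelic counts are keyed on ``snp_id`` (not position) so that count tables
are independent of the genome build; positions travel on :class:`HetSNP`.

A missing allele frequency is represented as *absent* (the SNP simply has no
row in the frequency table), never as 0 — absence itself classifies a
variant as rare downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class CatalogSource(str, Enum):
    GWAS = "gwas"
    EQTL = "eqtl"


class DuplicatedHaplotype(str, Enum):
    """Which haplotype carries the extra copy in a 3-copy CNV."""

    G1 = "g1"
    G2 = "g2"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HetSNP:
    """A heterozygous biallelic SNV in one cell line.

    ``pos`` is 0-based; ``ref_allele``/``alt_allele`` are the G1 (reference)
    and G2 (alternative) bases.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    cell_line: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class AllelicCountRecord:
    """ChIP-seq reads supporting each allele of one SNP in one dataset.

    ``dataset_id`` names the assay (TF, polymerase or coactivator plus cell
    line, e.g. ``CTCF_GM12878``); ``g1_count``/``g2_count`` are reads mapped
    specifically to the reference (G1) and alternative (G2) allele.
    """

    snp_id: str
    dataset_id: str
    g1_count: int
    g2_count: int

    def __post_init__(self) -> None:
        for name in ("g1_count", "g2_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class FrequencyRecord:
    snp_id: str
    af: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af must be in [0, 1], got {self.af}")


@dataclass(frozen=True)
class CatalogRecord:
    """One SNP-trait association from a GWAS or eQTL catalog."""

    snp_id: str
    trait: str
    source: CatalogSource
    chrom: str
    pos: int


@dataclass(frozen=True)
class ProxyRecord:
    """LD link between an index (catalog) SNP and a proxy SNP."""

    index_snp_id: str
    proxy_snp_id: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")


@dataclass(frozen=True)
class CNVRegion:
    """Copy-number variant region.

    ``copy_number`` is ``None`` for regions known to be CNV but without a
    genotyped copy number; SNPs inside those are excluded downstream.
    ``haplotype_resolved`` is true when the duplicated haplotype of a 3-copy
    region is known, which permits testing at an adjusted 2:1 null instead of
    discarding the SNP.
    """

    interval: GenomicInterval
    copy_number: Optional[int]
    duplicated_haplotype: DuplicatedHaplotype = DuplicatedHaplotype.UNKNOWN

    def __post_init__(self) -> None:
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")

    @property
    def haplotype_resolved(self) -> bool:
        return self.duplicated_haplotype is not DuplicatedHaplotype.UNKNOWN


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_het_snps(path: str | Path, cell_line: Optional[str] = None) -> list[HetSNP]:
    """Read heterozygous biallelic SNVs from a single-sample VCF.

    Only records with genotype 0/1 or 0|1 are returned.  Multiallelic
    records are skipped (a count is logged); indels and other non-SNV
    records are skipped silently.  VCF 1-based POS becomes internal 0-based
    ``pos``.  ``cell_line`` defaults to the VCF sample name.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if cell_line is None:
        cell_line = vcf.samples[0] if vcf.samples else "unknown"
    out: list[HetSNP] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if not v.is_snp:
            continue
        gt = v.genotypes[0]
        if sorted(gt[:2]) != [0, 1]:
            continue
        snp_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        out.append(
            HetSNP(
                snp_id=snp_id,
                chrom=v.CHROM,
                pos=v.POS - 1,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                cell_line=cell_line,
            )
        )
    if n_multi:
        logger.info("skipped %d multiallelic records in %s", n_multi, path)
    vcf.close()
    return out


def write_het_snps(snps: Sequence[HetSNP], path: str | Path, sample: Optional[str] = None) -> None:
    """Write heterozygous SNVs as a minimal single-sample VCF (GT=0|1)."""
    snps = list(snps)
    if sample is None:
        sample = snps[0].cell_line if snps else "sample"
    chroms = []
    for s in snps:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            # contig length unknown here; a generous bound keeps parsers happy
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for s in sorted(snps, key=lambda x: (chroms.index(x.chrom), x.pos)):
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\tPASS\t.\tGT\t0|1\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; coordinates (0-based half-open) pass through unchanged."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            label = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(chrom, start, end, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")


def read_cnv_regions(path: str | Path) -> list[CNVRegion]:
    """Read CNVs from a BED file with two extra columns.

    Columns: chrom, start, end, copy_number, duplicated_haplotype.
    ``copy_number`` of ``.`` marks a region known to be CNV but not genotyped;
    ``duplicated_haplotype`` is one of g1/g2/unknown.
    """
    out: list[CNVRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns for CNV BED")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            cn = None if parts[3] == "." else int(parts[3])
            try:
                hap = DuplicatedHaplotype(parts[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: duplicated_haplotype must be g1/g2/unknown"
                ) from exc
            out.append(CNVRegion(GenomicInterval(chrom, start, end), cn, hap))
    return out


def write_cnv_regions(cnvs: Iterable[CNVRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cnvs:
            cn = "." if c.copy_number is None else str(c.copy_number)
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{cn}\t{c.duplicated_haplotype.value}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _parse_int(value: str, what: str, where: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValueError(f"{where}: {what} must be an integer, got {value!r}") from None


def read_counts_table(path: str | Path) -> list[AllelicCountRecord]:
    """Read per-(SNP, dataset) allelic read counts.

    Duplicate (snp_id, dataset_id) keys and negative or non-integer counts
    are errors.
    """
    df = _read_tsv(path, ["snp_id", "dataset_id", "g1_count", "g2_count"])
    dup = df.duplicated(subset=["snp_id", "dataset_id"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["snp_id", "dataset_id"]].tolist()
        raise ValueError(f"{path}: duplicate (snp_id, dataset_id) key {tuple(key)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        g1 = _parse_int(row.g1_count, "g1_count", f"{path} row {i}")
        g2 = _parse_int(row.g2_count, "g2_count", f"{path} row {i}")
        if g1 < 0 or g2 < 0:
            raise ValueError(f"{path} row {i}: negative count")
        out.append(AllelicCountRecord(row.snp_id, row.dataset_id, g1, g2))
    return out


def write_counts_table(records: Iterable[AllelicCountRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.snp_id, r.dataset_id, r.g1_count, r.g2_count) for r in records],
        columns=["snp_id", "dataset_id", "g1_count", "g2_count"],
    ).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | Path) -> dict[str, float]:
    """Read snp_id -> alternative-allele frequency.

    SNPs with no row are *absent*; downstream that alone classifies them rare.
    """
    df = _read_tsv(path, ["snp_id", "af"])
    out: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            af = float(row.af)
        except (TypeError, ValueError):
            raise ValueError(f"{path} row {i}: af not numeric: {row.af!r}") from None
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"{path} row {i}: af outside [0, 1]: {af}")
        out[row.snp_id] = af
    return out


def write_frequency_table(freqs: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(sorted(freqs.items()), columns=["snp_id", "af"]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog(path: str | Path) -> list[CatalogRecord]:
    df = _read_tsv(path, ["snp_id", "trait", "source", "chrom", "pos"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            source = CatalogSource(row.source)
        except ValueError:
            raise ValueError(f"{path} row {i}: source must be gwas or eqtl") from None
        out.append(
            CatalogRecord(row.snp_id, row.trait, source, row.chrom, _parse_int(row.pos, "pos", f"{path} row {i}"))
        )
    return out


def write_catalog(records: Iterable[CatalogRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.snp_id, r.trait, r.source.value, r.chrom, r.pos) for r in records],
        columns=["snp_id", "trait", "source", "chrom", "pos"],
    ).to_csv(path, sep="\t", index=False)


def read_proxy_table(path: str | Path) -> list[ProxyRecord]:
    df = _read_tsv(path, ["index_snp_id", "proxy_snp_id", "r2"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            r2 = float(row.r2)
        except (TypeError, ValueError):
            raise ValueError(f"{path} row {i}: r2 not numeric") from None
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"{path} row {i}: r2 outside [0, 1]: {r2}")
        out.append(ProxyRecord(row.index_snp_id, row.proxy_snp_id, r2))
    return out


def write_proxy_table(records: Iterable[ProxyRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.index_snp_id, r.proxy_snp_id, r.r2) for r in records],
        columns=["index_snp_id", "proxy_snp_id", "r2"],
    ).to_csv(path, sep="\t", index=False)


def counts_to_frame(records: Sequence[AllelicCountRecord]) -> pd.DataFrame:
    """Canonical DataFrame view of a count collection (one row per record)."""
    return pd.DataFrame(
        [(r.snp_id, r.dataset_id, r.g1_count, r.g2_count) for r in records],
        columns=["snp_id", "dataset_id", "g1_count", "g2_count"],
    )
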