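"""Truth-labelled synthetic inputs with the statistical structure the
pipeline assumes.

The generator emulates one cell line: heterozygous SNVs placed uniformly on
a toy genome, population allele frequencies with a configurable rare
(AF < 1 %) fraction, per-(SNP, dataset) allelic read counts that are
binomial around a true G1 fraction theta (0.5 under the null), CNV regions
that shift the expected allelic ratio to 2:1 on the duplicated haplotype,
gap/blacklist masks, and GWAS/eQTL catalogs with planted LD proxy links.
Rare AS-SNPs draw theta farther from 0.5 than common ones, mirroring the
larger regulatory effect expected of rare variants.

Every operation is deterministic given the config seed; the same config
yields a byte-identical fixture bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .variant_io import (
    CNVRegion,
    CatalogRecord,
    CatalogSource,
    DuplicatedHaplotype,
    GenomicInterval,
    HetSNP,
    ProxyRecord,
    write_bed,
    write_catalog,
    write_cnv_regions,
    write_counts_table,
    write_frequency_table,
    write_het_snps,
    write_proxy_table,
)
from ._intervals import RegionLookup

_BASES = np.array(list("ACGT"))


@dataclass
class DepthModel:
    """Total read depth per (SNP, dataset).

    ChIP-seq depths are overdispersed, so the default is a negative
    binomial (mean 30, dispersion 5); a Poisson is available for analytic
    checks.
    """

    distribution: str = "negative_binomial"
    mean: float = 30.0
    dispersion: float = 5.0

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.mean <= 0:
            raise ValueError("depth mean must be positive")
        if self.distribution == "poisson":
            return rng.poisson(self.mean, size=shape)
        if self.distribution == "negative_binomial":
            r = self.dispersion
            return rng.negative_binomial(r, r / (r + self.mean), size=shape)
        raise ValueError(f"unknown depth distribution {self.distribution!r}")


@dataclass
class EffectModel:
    """Distribution of the true allelic shift |theta - 0.5| for AS-SNPs.

    The shift is uniform on [min_shift, max_shift] with a random sign.
    """

    min_shift: float = 0.10
    max_shift: float = 0.25

    def draw_theta(self, rng: np.random.Generator, size: int) -> np.ndarray:
        shift = rng.uniform(self.min_shift, self.max_shift, size=size)
        sign = rng.choice([-1.0, 1.0], size=size)
        return np.clip(0.5 + sign * shift, 1e-6, 1.0 - 1e-6)


@dataclass
class CNVConfig:
    n_regions: int = 4
    copy_numbers: tuple = (2, 3, 3, 4)  # drawn uniformly; None = ungenotyped
    region_length: int = 500_000
    frac_haplotype_resolved: float = 1.0


@dataclass
class MaskConfig:
    n_gap: int = 1
    n_blacklist: int = 3
    gap_length: int = 50_000
    blacklist_length: int = 1_000


@dataclass
class CatalogConfig:
    n_gwas: int = 15
    n_eqtl: int = 15
    n_traits: int = 6
    frac_direct: float = 0.2       # catalog entries placed on simulated SNPs
    frac_as_linked: float = 0.3    # true-AS SNPs given a proxy link (r2 > 0.8)
    n_decoy_links: int = 20        # links at r2 <= 0.8 that must not survive


@dataclass
class SimulationConfig:
    seed: int = 0
    n_snps: int = 2000
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 20_000_000}
    )
    n_datasets: int = 3
    cell_line: str = "SIMCELL"
    depth_model: DepthModel = field(default_factory=DepthModel)
    frac_as: float = 0.10
    common_effect: EffectModel = field(default_factory=lambda: EffectModel(0.10, 0.25))
    rare_effect: EffectModel = field(default_factory=lambda: EffectModel(0.20, 0.45))
    frac_rare: float = 0.14        # AF < 1 %, matching the het-SNP background
    af_absent_prob: float = 0.5    # rare SNP missing from the frequency table
    ref_bias: float = 1.0          # multiplies theta_eff; 1.0 = no reference bias
    cnv: CNVConfig = field(default_factory=CNVConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    catalog: CatalogConfig = field(default_factory=CatalogConfig)

    def __post_init__(self) -> None:
        for name in ("frac_as", "frac_rare", "af_absent_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["depth_model"] = DepthModel(**raw["depth_model"])
        for key in ("common_effect", "rare_effect"):
            raw[key] = EffectModel(**raw[key])
        raw["cnv"] = CNVConfig(**{**raw["cnv"], "copy_numbers": tuple(raw["cnv"]["copy_numbers"])})
        raw["mask"] = MaskConfig(**raw["mask"])
        raw["catalog"] = CatalogConfig(**raw["catalog"])
        return cls(**raw)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generation stage
    return np.random.default_rng([config.seed, stream])


def generate_het_snps(
    config: SimulationConfig,
) -> tuple[list[HetSNP], dict[str, float], pd.DataFrame]:
    """Place heterozygous SNVs and assign allele frequencies and AS labels.

    Returns the SNPs, the (possibly incomplete) frequency table, and a
    truth skeleton with one row per SNP: snp_id, chrom, pos, af, is_rare,
    is_as, af_absent.  Rare SNPs are dropped from the frequency table with
    probability ``af_absent_prob`` but keep their true AF in the skeleton.
    """
    rng = _rng(config, 0)
    total = sum(config.chrom_sizes.values())
    if config.n_snps > total:
        raise ValueError(f"n_snps={config.n_snps} exceeds genome length {total}")

    chroms = sorted(config.chrom_sizes)
    weights = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(config.n_snps, weights / weights.sum())
    while any(alloc[i] > config.chrom_sizes[c] for i, c in enumerate(chroms)):
        alloc = rng.multinomial(config.n_snps, weights / weights.sum())

    rows = []
    for i, chrom in enumerate(chroms):
        k = int(alloc[i])
        if k == 0:
            continue
        length = config.chrom_sizes[chrom]
        pos = np.array([], dtype=np.int64)
        while len(pos) < k:
            cand = np.unique(rng.integers(0, length, size=max(2 * k, 100)))
            pos = cand if len(cand) >= k else pos
        pos = np.sort(pos[rng.permutation(len(pos))[:k]])
        for p in pos:
            rows.append((chrom, int(p)))

    n = len(rows)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    is_rare = rng.random(n) < config.frac_rare
    af = np.where(
        is_rare,
        rng.uniform(1e-4, 0.01, size=n),
        rng.uniform(0.01, 0.5, size=n),
    )
    af_absent = is_rare & (rng.random(n) < config.af_absent_prob)
    is_as = rng.random(n) < config.frac_as

    snps: list[HetSNP] = []
    freq: dict[str, float] = {}
    truth_rows = []
    for i, (chrom, pos) in enumerate(rows):
        snp_id = f"snp{i:06d}"
        snps.append(
            HetSNP(snp_id, chrom, pos, str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]), config.cell_line)
        )
        if not af_absent[i]:
            freq[snp_id] = round(float(af[i]), 6)
        truth_rows.append((snp_id, chrom, pos, float(af[i]), bool(is_rare[i]), bool(is_as[i]), bool(af_absent[i])))
    truth = pd.DataFrame(
        truth_rows, columns=["snp_id", "chrom", "pos", "af", "is_rare", "is_as", "af_absent"]
    )
    return snps, freq, truth


def generate_cnv_and_mask_regions(
    config: SimulationConfig,
) -> tuple[list[CNVRegion], list[GenomicInterval], list[GenomicInterval]]:
    """Draw non-overlapping CNV, gap and blacklist regions on the toy genome.

    Placement is rejection sampling; if the requested regions cannot be
    placed without overlap in 1000 attempts the call errors (the documented
    capacity policy — no silent truncation).
    """
    rng = _rng(config, 1)
    chroms = sorted(config.chrom_sizes)
    placed: list[GenomicInterval] = []

    def place(length: int, label: str) -> GenomicInterval:
        for _ in range(1000):
            chrom = chroms[rng.integers(0, len(chroms))]
            size = config.chrom_sizes[chrom]
            if size <= length:
                continue
            start = int(rng.integers(0, size - length))
            iv = GenomicInterval(chrom, start, start + length, label)
            if all(iv.chrom != o.chrom or iv.end <= o.start or o.end <= iv.start for o in placed):
                placed.append(iv)
                return iv
        raise ValueError(f"could not place a {length} bp {label} region without overlap")

    cnvs: list[CNVRegion] = []
    for _ in range(config.cnv.n_regions):
        iv = place(config.cnv.region_length, "cnv")
        cn = config.cnv.copy_numbers[rng.integers(0, len(config.cnv.copy_numbers))]
        hap = DuplicatedHaplotype.UNKNOWN
        if cn == 3 and rng.random() < config.cnv.frac_haplotype_resolved:
            hap = DuplicatedHaplotype.G1 if rng.random() < 0.5 else DuplicatedHaplotype.G2
        cnvs.append(CNVRegion(GenomicInterval(iv.chrom, iv.start, iv.end), cn, hap))
    gaps = [place(config.mask.gap_length, "gap") for _ in range(config.mask.n_gap)]
    blacklist = [place(config.mask.blacklist_length, "blacklist") for _ in range(config.mask.n_blacklist)]
    return cnvs, gaps, blacklist


def _theta_with_copies(theta: np.ndarray, g1_copies: np.ndarray, total_copies: np.ndarray) -> np.ndarray:
    """Per-copy read fraction when the G1 haplotype holds ``g1_copies`` of
    ``total_copies`` chromosomal copies.  A balanced SNP (theta = 0.5) in a
    2:1 region lands exactly on 2/3 (or 1/3)."""
    num = g1_copies * theta
    return num / (num + (total_copies - g1_copies) * (1.0 - theta))


def simulate_allelic_counts(
    snps: list[HetSNP],
    truth: pd.DataFrame,
    cnvs: list[CNVRegion],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-(SNP, dataset) allelic read counts.

    The true G1 fraction theta is 0.5 for non-AS SNPs and comes from the
    common/rare effect model for AS SNPs.  Inside a CNV the realised read
    fraction is rescaled by the haplotype copy numbers, so a non-AS SNP in
    a resolved 3-copy region sits at 2/3 or 1/3 according to the duplicated
    haplotype.  SNPs in unresolved or high-copy CNVs still receive counts
    (excluding them is the pipeline's job): the simulator privately assigns
    the G1 haplotype 1..(cn-1) of the copies.  Returns a counts DataFrame
    (snp_id, dataset_id, g1_count, g2_count) and the completed truth table
    with columns true_theta, theta_eff and in_cnv added.
    """
    rng = _rng(config, 2)
    truth = truth.copy()
    n = len(truth)
    if [s.snp_id for s in snps] != list(truth["snp_id"]):
        raise ValueError("snps and truth must be aligned by snp_id")

    theta = np.full(n, 0.5)
    as_mask = truth["is_as"].to_numpy()
    rare_mask = truth["is_rare"].to_numpy()
    idx_common = np.flatnonzero(as_mask & ~rare_mask)
    idx_rare = np.flatnonzero(as_mask & rare_mask)
    theta[idx_common] = config.common_effect.draw_theta(rng, len(idx_common))
    theta[idx_rare] = config.rare_effect.draw_theta(rng, len(idx_rare))

    lookup = RegionLookup(cnvs, key=lambda c: c.interval)
    theta_eff = theta.copy()
    in_cnv = np.zeros(n, dtype=bool)
    for i, snp in enumerate(snps):
        hits = lookup.overlapping(snp.chrom, snp.pos)
        if not hits:
            continue
        cnv = hits[0]
        in_cnv[i] = True
        cn = cnv.copy_number if cnv.copy_number is not None else 3
        if cn == 2:
            continue
        if cn < 2:
            continue  # het call in a deletion; leave counts diploid-like
        if cn == 3 and cnv.duplicated_haplotype is DuplicatedHaplotype.G1:
            g1_copies = 2
        elif cn == 3 and cnv.duplicated_haplotype is DuplicatedHaplotype.G2:
            g1_copies = 1
        else:
            g1_copies = int(rng.integers(1, cn))
        theta_eff[i] = _theta_with_copies(
            np.array(theta[i]), np.array(float(g1_copies)), np.array(float(cn))
        )
    if config.ref_bias != 1.0:
        theta_eff = np.clip(theta_eff * config.ref_bias, 0.0, 1.0)

    depth = config.depth_model.draw(rng, (n, config.n_datasets))
    g1 = rng.binomial(depth, theta_eff[:, None])
    g2 = depth - g1

    datasets = [f"TF{j + 1:02d}_{config.cell_line}" for j in range(config.n_datasets)]
    counts = pd.DataFrame(
        {
            "snp_id": np.repeat(truth["snp_id"].to_numpy(), config.n_datasets),
            "dataset_id": np.tile(np.array(datasets), n),
            "g1_count": g1.ravel(),
            "g2_count": g2.ravel(),
        }
    )
    truth["true_theta"] = theta
    truth["theta_eff"] = theta_eff
    truth["in_cnv"] = in_cnv
    return counts, truth


def generate_catalog_and_proxies(
    snps: list[HetSNP],
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[list[CatalogRecord], list[ProxyRecord]]:
    """Plant GWAS/eQTL catalog SNPs and LD proxy links.

    A fraction of catalog entries sit directly on simulated SNPs (potential
    direct hits); a configurable fraction of true-AS SNPs get a proxy link
    at r2 > 0.8 to a random index SNP (many-to-many topologies arise
    naturally), and decoy links at r2 <= 0.8 are added that must not
    survive the downstream threshold.
    """
    if not snps:
        raise ValueError("snps must be non-empty")
    rng = _rng(config, 3)
    cat = config.catalog
    snp_ids = truth["snp_id"].to_numpy()
    as_ids = truth.loc[truth["is_as"], "snp_id"].to_numpy()
    non_as_ids = truth.loc[~truth["is_as"], "snp_id"].to_numpy()
    traits = [f"trait{t:02d}" for t in range(cat.n_traits)]
    chroms = sorted(config.chrom_sizes)

    records: list[CatalogRecord] = []
    for j in range(cat.n_gwas + cat.n_eqtl):
        source = CatalogSource.GWAS if j < cat.n_gwas else CatalogSource.EQTL
        trait = traits[int(rng.integers(0, len(traits)))]
        if rng.random() < cat.frac_direct and len(snp_ids):
            i = int(rng.integers(0, len(snp_ids)))
            snp = snps[i]
            records.append(CatalogRecord(snp.snp_id, trait, source, snp.chrom, snp.pos))
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, config.chrom_sizes[chrom]))
            records.append(CatalogRecord(f"idx{j:04d}", trait, source, chrom, pos))

    proxies: list[ProxyRecord] = []
    n_linked = int(round(cat.frac_as_linked * len(as_ids)))
    if n_linked and records:
        linked = rng.choice(as_ids, size=n_linked, replace=False)
        for snp_id in linked:
            index = records[int(rng.integers(0, len(records)))]
            proxies.append(ProxyRecord(index.snp_id, str(snp_id), round(float(rng.uniform(0.805, 0.999)), 3)))
    if cat.n_decoy_links and records and len(non_as_ids):
        decoys = rng.choice(non_as_ids, size=min(cat.n_decoy_links, len(non_as_ids)), replace=False)
        for snp_id in decoys:
            index = records[int(rng.integers(0, len(records)))]
            proxies.append(ProxyRecord(index.snp_id, str(snp_id), round(float(rng.uniform(0.2, 0.8)), 3)))
    return records, proxies


@dataclass
class Bundle:
    """In-memory synthetic dataset: everything one pipeline run consumes."""

    config: SimulationConfig
    snps: list[HetSNP]
    frequencies: dict[str, float]
    truth: pd.DataFrame
    cnvs: list[CNVRegion]
    gaps: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    counts: pd.DataFrame
    catalog: list[CatalogRecord]
    proxies: list[ProxyRecord]


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Run every generation stage with the config's seed."""
    snps, freq, truth = generate_het_snps(config)
    cnvs, gaps, blacklist = generate_cnv_and_mask_regions(config)
    counts, truth = simulate_allelic_counts(snps, truth, cnvs, config)
    catalog, proxies = generate_catalog_and_proxies(snps, truth, config)
    return Bundle(config, snps, freq, truth, cnvs, gaps, blacklist, counts, catalog, proxies)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_fixture_bundle(output_dir: str | Path, config: SimulationConfig) -> pd.DataFrame:
    """Write a complete fixture bundle in the pipeline's input formats.

    Produces snps.vcf, counts.tsv, frequencies.tsv, cnvs.bed, gaps.bed,
    blacklist.bed, catalog.tsv, proxies.tsv, truth.tsv and config.yaml, plus
    manifest.tsv listing each file with its SHA-256 checksum.  Identical
    configs yield identical checksums.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = generate_bundle(config)
    write_het_snps(b.snps, outdir / "snps.vcf")
    b.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    write_frequency_table(b.frequencies, outdir / "frequencies.tsv")
    write_cnv_regions(b.cnvs, outdir / "cnvs.bed")
    write_bed(b.gaps, outdir / "gaps.bed")
    write_bed(b.blacklist, outdir / "blacklist.bed")
    write_catalog(b.catalog, outdir / "catalog.tsv")
    write_proxy_table(b.proxies, outdir / "proxies.tsv")
    b.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")

    names = [
        "snps.vcf", "counts.tsv", "frequencies.tsv", "cnvs.bed", "gaps.bed",
        "blacklist.bed", "catalog.tsv", "proxies.tsv", "truth.tsv", "config.yaml",
    ]
    manifest = pd.DataFrame(
        [(name, _sha256(outdir / name)) for name in names], columns=["file", "sha256"]
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
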