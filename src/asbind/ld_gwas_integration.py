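"""LD proxy expansion, catalog intersection, locus grouping and enrichment.

GWAS and eQTL catalogs report index SNPs, but the functional variant is
often a different SNP on the same haplotype.  Each catalog association is
therefore expanded with its LD proxies at r^2 strictly above 0.8 before
intersecting with the AS-SNP collection; an AS-SNP is a *direct* hit when
it is itself a catalog SNP and an *LD* hit when it is only reachable
through a proxy.  Index hits are grouped into loci by single-linkage
chaining within 1 Mb, and enrichment over chance is assessed by redrawing
matched random sets of non-AS heterozygous SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._intervals import PointLookup
from .variant_io import CatalogRecord, GenomicInterval, ProxyRecord

logger = logging.getLogger(__name__)


@dataclass
class ExpandedAssociation:
    """A catalog association plus every proxy SNP in high LD with its index."""

    index_snp: CatalogRecord
    linked_snps: set[tuple[str, float]] = field(default_factory=set)

    @property
    def trait(self) -> str:
        return self.index_snp.trait

    def member_ids(self) -> set[str]:
        return {snp_id for snp_id, _ in self.linked_snps}


@dataclass(frozen=True)
class LocusGroup:
    trait: str
    chrom: str
    member_index_snps: tuple[str, ...]
    span: GenomicInterval


@dataclass
class NetworkSummary:
    """Bipartite AS-SNP <-> catalog-SNP overlap with full edge retention."""

    n_direct_hits: int
    n_ld_hits: int
    edges: list[tuple[str, str, float, str]]  # (as_snp, index_snp, r2, trait)
    as_degree: dict[str, int]
    index_degree: dict[str, int]
    direct_hit_ids: set[str]
    ld_hit_ids: set[str]


@dataclass
class EnrichmentResult:
    observed_overlap: int
    null_overlaps: np.ndarray
    fold: float
    empirical_p: float
    n_permutations: int
    seed: int
    fold_infinite: bool = False


def r_squared(hap_a: Sequence[int], hap_b: Sequence[int]) -> float:
    """Squared LD correlation between two biallelic sites from phased haplotypes.

    ``hap_a`` and ``hap_b`` are equal-length 0/1 vectors, one entry per
    haplotype.  r^2 = D^2 / (pA(1-pA) pB(1-pB)) with D = pAB - pA*pB.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length haplotype vectors of >= 2 haplotypes")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("r^2 undefined for a monomorphic site")
    d = (a * b).mean() - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def expand_with_proxies(
    catalog: Sequence[CatalogRecord],
    proxy_table: Sequence[ProxyRecord],
    threshold: float = 0.8,
) -> list[ExpandedAssociation]:
    """Attach proxies with r^2 strictly above ``threshold`` to each association.

    The index SNP always belongs to its own expansion (r^2 = 1 by
    convention).  Proxies referencing an unknown index are dropped with a
    warning.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    by_index: dict[str, list[ExpandedAssociation]] = {}
    out = []
    for rec in catalog:
        assoc = ExpandedAssociation(index_snp=rec, linked_snps={(rec.snp_id, 1.0)})
        by_index.setdefault(rec.snp_id, []).append(assoc)
        out.append(assoc)
    n_dropped = 0
    for proxy in proxy_table:
        targets = by_index.get(proxy.index_snp_id)
        if targets is None:
            n_dropped += 1
            continue
        if proxy.r2 > threshold:
            for assoc in targets:
                assoc.linked_snps.add((proxy.proxy_snp_id, proxy.r2))
    if n_dropped:
        logger.warning("dropped %d proxy records with unknown index SNPs", n_dropped)
    return out


def intersect_as_with_catalog(
    as_snp_ids: set[str], expansions: Sequence[ExpandedAssociation]
) -> NetworkSummary:
    """Classify AS-SNPs as direct catalog hits or LD-linked and keep all edges."""
    index_ids = {e.index_snp.snp_id for e in expansions}
    edges: list[tuple[str, str, float, str]] = []
    hit_ids: set[str] = set()
    for assoc in expansions:
        for snp_id, r2 in assoc.linked_snps:
            if snp_id in as_snp_ids:
                edges.append((snp_id, assoc.index_snp.snp_id, r2, assoc.trait))
                hit_ids.add(snp_id)
    direct = hit_ids & index_ids
    ld_only = hit_ids - index_ids
    as_degree: dict[str, int] = {}
    index_degree: dict[str, int] = {}
    for as_snp, index_snp, _, _ in edges:
        as_degree[as_snp] = as_degree.get(as_snp, 0) + 1
        index_degree[index_snp] = index_degree.get(index_snp, 0) + 1
    return NetworkSummary(
        n_direct_hits=len(direct),
        n_ld_hits=len(ld_only),
        edges=edges,
        as_degree=as_degree,
        index_degree=index_degree,
        direct_hit_ids=direct,
        ld_hit_ids=ld_only,
    )


def group_into_loci(
    index_hits: Sequence[CatalogRecord], window: int = 1_000_000
) -> list[LocusGroup]:
    """Chain index SNPs of one trait into loci by single linkage within ``window``.

    Consecutive index SNPs on the same chromosome at most ``window`` apart
    join the same locus; the locus span runs from the first to one past the
    last member position.  Input order does not matter.
    """
    groups: dict[tuple[str, str], list[CatalogRecord]] = {}
    for rec in index_hits:
        groups.setdefault((rec.trait, rec.chrom), []).append(rec)
    loci: list[LocusGroup] = []
    for (trait, chrom), recs in sorted(groups.items()):
        recs = sorted(recs, key=lambda r: (r.pos, r.snp_id))
        chain: list[CatalogRecord] = [recs[0]]
        for rec in recs[1:]:
            if rec.pos - chain[-1].pos <= window:
                chain.append(rec)
            else:
                loci.append(_make_locus(trait, chrom, chain))
                chain = [rec]
        loci.append(_make_locus(trait, chrom, chain))
    return loci


def _make_locus(trait: str, chrom: str, members: list[CatalogRecord]) -> LocusGroup:
    return LocusGroup(
        trait=trait,
        chrom=chrom,
        member_index_snps=tuple(m.snp_id for m in members),
        span=GenomicInterval(chrom, members[0].pos, members[-1].pos + 1),
    )


def target_ids_from_expansions(expansions: Sequence[ExpandedAssociation]) -> set[str]:
    """All SNP ids reachable through a catalog expansion (index + proxies)."""
    out: set[str] = set()
    for e in expansions:
        out |= e.member_ids()
    return out


def target_ids_from_intervals(
    intervals: Sequence[GenomicInterval], positions: Mapping[str, tuple[str, int]]
) -> set[str]:
    """SNP ids whose (chrom, pos) falls inside any target interval."""
    lookup = PointLookup(intervals)
    return {snp for snp, (chrom, pos) in positions.items() if lookup.contains(chrom, pos)}


def permutation_enrichment(
    as_snps: set[str],
    candidate_pool: Sequence[str],
    target_ids: set[str],
    n_permutations: int,
    seed: int,
    matching: str = "count_only",
    af_table: Optional[Mapping[str, float]] = None,
) -> EnrichmentResult:
    """Enrichment of AS-SNPs in a target set versus matched random draws.

    Each permutation draws ``len(as_snps)`` SNPs from the non-AS candidate
    pool without replacement — within allele-frequency deciles when
    ``matching="af_matched"`` — and records the overlap with ``target_ids``.
    fold = observed / mean(null); empirical p uses the add-one rule
    (1 + #{null >= observed}) / (1 + n_permutations), so it is never 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(candidate_pool) < len(as_snps):
        raise ValueError(
            f"candidate pool ({len(candidate_pool)}) smaller than AS set ({len(as_snps)})"
        )
    if matching not in ("count_only", "af_matched"):
        raise ValueError(f"matching must be count_only or af_matched, got {matching}")
    rng = np.random.default_rng(seed)
    pool = np.asarray(sorted(candidate_pool))
    in_target_pool = np.isin(pool, sorted(target_ids))
    observed = len(as_snps & target_ids)

    if matching == "af_matched":
        if af_table is None:
            raise ValueError("af_matched requires af_table")
        null = _af_matched_nulls(as_snps, pool, in_target_pool, af_table, n_permutations, rng)
    else:
        k = len(as_snps)
        null = np.empty(n_permutations, dtype=np.int64)
        for i in range(n_permutations):
            idx = rng.choice(len(pool), size=k, replace=False)
            null[i] = int(in_target_pool[idx].sum())

    mean_null = float(null.mean())
    fold_infinite = mean_null == 0.0 and observed > 0
    fold = float("inf") if fold_infinite else (observed / mean_null if mean_null else 0.0)
    empirical_p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    return EnrichmentResult(
        observed_overlap=observed,
        null_overlaps=null,
        fold=fold,
        empirical_p=empirical_p,
        n_permutations=n_permutations,
        seed=seed,
        fold_infinite=fold_infinite,
    )


def _af_matched_nulls(
    as_snps: set[str],
    pool: np.ndarray,
    in_target_pool: np.ndarray,
    af_table: Mapping[str, float],
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null overlaps drawing within AF deciles matching the AS set profile."""
    edges = np.linspace(0.0, 1.0, 11)

    def decile(snp: str) -> int:
        af = af_table.get(snp, 0.0)  # absent = rare, lowest bin
        return min(9, int(np.searchsorted(edges, af, side="right") - 1))

    as_bins = np.array([decile(s) for s in sorted(as_snps)])
    pool_bins = np.array([decile(s) for s in pool])
    need = np.bincount(as_bins, minlength=10)
    bin_members = [np.flatnonzero(pool_bins == b) for b in range(10)]
    for b in range(10):
        if need[b] > len(bin_members[b]):
            raise ValueError(f"AF decile {b}: pool has {len(bin_members[b])} SNPs, need {need[b]}")
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        total = 0
        for b in range(10):
            if need[b]:
                idx = rng.choice(bin_members[b], size=need[b], replace=False)
                total += int(in_target_pool[idx].sum())
        null[i] = total
    return null
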