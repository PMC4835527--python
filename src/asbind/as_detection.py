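"""Statistical core: exact binomial tests with CNV-adjusted nulls and FDR.

Each heterozygous SNP x ChIP-seq dataset pair is tested for allelic
imbalance with an exact two-sided binomial test of the G1 read count
against a null proportion that is 1/2 for diploid sites and 1/3 or 2/3 for
sites inside a haplotype-resolved three-copy CNV (the duplicated haplotype
contributes two of three chromosomal copies).  SNPs inside unresolved
three-copy, ungenotyped, or >= four-copy CNV regions are not testable.
P-values are corrected with Benjamini-Hochberg, by default within each
dataset family; a SNP is called allele-specific (AS) when significant in at
least one dataset.

The two-sided p-value uses the minimum-likelihood convention: with
``n = g1 + g2`` and ``X ~ Binomial(n, null_p)``, it sums ``Pr(X = k)`` over
every outcome no more likely than the observed one (a relative tolerance of
1e-12 guards float ties).  For a symmetric null this equals the doubled
tail capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._intervals import RegionLookup
from .variant_io import (
    AllelicCountRecord,
    CNVRegion,
    DuplicatedHaplotype,
    HetSNP,
    counts_to_frame,
)

_TIE_EPS = 1e-12


class NullVerdict(str, Enum):
    TESTABLE = "testable"
    EXCLUDED_UNRESOLVED_CNV = "excluded_unresolved_cnv"
    EXCLUDED_HIGH_COPY = "excluded_high_copy"
    EXCLUDED_UNGENOTYPED_CNV = "excluded_ungenotyped_cnv"


@dataclass(frozen=True)
class NullSpec:
    """Binomial null proportion for a SNP after CNV adjustment, or exclusion."""

    snp_id: str
    verdict: NullVerdict
    null_p: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.verdict is NullVerdict.TESTABLE) != (self.null_p is not None):
            raise ValueError("null_p must be set iff verdict is testable")


@dataclass(frozen=True)
class ASTestResult:
    snp_id: str
    dataset_id: str
    g1_count: int
    g2_count: int
    null_p: float
    p_value: float
    q_value: float
    significant: bool


@lru_cache(maxsize=4096)
def _sorted_pmf(n: int, null_p: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-outcome pmf, its ascending sort, and the cumsum of the sort."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, null_p)
    order = np.sort(pmf)
    return pmf, order, np.cumsum(order)


def two_sided_binomial_p(g1: int, g2: int, null_p: float) -> float:
    """Exact two-sided binomial p-value for counts (g1, g2) under ``null_p``.

    Sums the probabilities of all outcomes whose likelihood does not exceed
    the observed outcome's (relative tolerance 1e-12).
    """
    if g1 < 0 or g2 < 0:
        raise ValueError(f"counts must be non-negative, got ({g1}, {g2})")
    if not (0.0 < null_p < 1.0):
        raise ValueError(f"null_p must be in (0, 1), got {null_p}")
    n = g1 + g2
    if n == 0:
        raise ValueError("total count must be positive")
    pmf, order, csum = _sorted_pmf(n, float(null_p))
    obs = pmf[g1] * (1.0 + _TIE_EPS)
    idx = np.searchsorted(order, obs, side="right") - 1
    p = float(csum[idx]) if idx >= 0 else 0.0
    return min(1.0, p)


def binomial_p_values(
    g1: np.ndarray, g2: np.ndarray, null_p: np.ndarray | float
) -> np.ndarray:
    """Vectorised :func:`two_sided_binomial_p` over arrays of counts."""
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    null_p = np.broadcast_to(np.asarray(null_p, dtype=float), g1.shape)
    n = g1 + g2
    out = np.empty(g1.shape, dtype=float)
    keys = np.stack([n, (null_p * 1e15).astype(np.int64)], axis=-1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    for grp in np.unique(inverse):
        mask = inverse == grp
        ni = int(n[mask][0])
        pi = float(null_p[mask][0])
        pmf, order, csum = _sorted_pmf(ni, pi)
        obs = pmf[g1[mask]] * (1.0 + _TIE_EPS)
        idx = np.searchsorted(order, obs, side="right") - 1
        vals = np.where(idx >= 0, csum[np.maximum(idx, 0)], 0.0)
        out[mask] = np.minimum(1.0, vals)
    return out


def resolve_null(snp: HetSNP, cnvs: Union[Sequence[CNVRegion], RegionLookup]) -> NullSpec:
    """Assign the CNV-adjusted null proportion (or an exclusion) to one SNP.

    Outside any CNV, or inside a 2-copy region, the null stays 1/2.  In a
    haplotype-resolved 3-copy region the expected allelic ratio is 2:1, so
    the null becomes 2/3 when the duplicated haplotype carries the G1 allele
    and 1/3 when it carries G2.  Unresolved 3-copy, ungenotyped, >= 4-copy,
    and sub-diploid regions (incompatible with a heterozygous genotype) all
    exclude the SNP from testing.
    """
    lookup = cnvs if isinstance(cnvs, RegionLookup) else RegionLookup(cnvs, key=lambda c: c.interval)
    hits: list[CNVRegion] = lookup.overlapping(snp.chrom, snp.pos)
    if not hits:
        return NullSpec(snp.snp_id, NullVerdict.TESTABLE, 0.5)
    copy_numbers = {c.copy_number for c in hits}
    if len(copy_numbers) > 1:
        raise ValueError(
            f"conflicting copy numbers {copy_numbers} for {snp.snp_id} at {snp.chrom}:{snp.pos}"
        )
    cnv = hits[0]
    if cnv.copy_number is None:
        return NullSpec(snp.snp_id, NullVerdict.EXCLUDED_UNGENOTYPED_CNV)
    if cnv.copy_number >= 4:
        return NullSpec(snp.snp_id, NullVerdict.EXCLUDED_HIGH_COPY)
    if cnv.copy_number == 2:
        return NullSpec(snp.snp_id, NullVerdict.TESTABLE, 0.5)
    if cnv.copy_number == 3:
        if not cnv.haplotype_resolved:
            return NullSpec(snp.snp_id, NullVerdict.EXCLUDED_UNRESOLVED_CNV)
        null_p = 2.0 / 3.0 if cnv.duplicated_haplotype is DuplicatedHaplotype.G1 else 1.0 / 3.0
        return NullSpec(snp.snp_id, NullVerdict.TESTABLE, null_p)
    # copy number 0/1 contradicts heterozygosity; treat like an ungenotyped call
    return NullSpec(snp.snp_id, NullVerdict.EXCLUDED_UNGENOTYPED_CNV)


def resolve_nulls(snps: Iterable[HetSNP], cnvs: Sequence[CNVRegion]) -> dict[str, NullSpec]:
    lookup = RegionLookup(cnvs, key=lambda c: c.interval)
    return {s.snp_id: resolve_null(s, lookup) for s in snps}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_as_snps(
    counts: Union[Sequence[AllelicCountRecord], pd.DataFrame],
    nullspecs: Mapping[str, NullSpec],
    alpha: float = 0.05,
    bh_family: str = "per_dataset",
) -> tuple[pd.DataFrame, set[str], dict[str, int]]:
    """Test every (SNP, dataset) pair and call AS-SNPs.

    Records with zero reads on either allele are discarded, as are records
    whose SNP is not testable under its :class:`NullSpec`.  Survivors are
    tested against their null proportion, BH-corrected within each
    ``dataset_id`` family (or globally with ``bh_family="global"``), and a
    SNP enters the AS set when ``q < alpha`` in at least one dataset.

    Returns ``(results, as_snp_ids, discarded)`` where ``results`` is one
    row per tested pair with columns snp_id, dataset_id, g1_count, g2_count,
    null_p, p_value, q_value, significant, and ``discarded`` counts the
    zero-allele and non-testable drops.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if bh_family not in ("per_dataset", "global"):
        raise ValueError(f"bh_family must be per_dataset or global, got {bh_family}")
    df = counts if isinstance(counts, pd.DataFrame) else counts_to_frame(counts)
    df = df.copy()

    zero_mask = (df["g1_count"] == 0) | (df["g2_count"] == 0)
    discarded = {"zero_allele": int(zero_mask.sum())}
    df = df[~zero_mask]

    missing = df["snp_id"][~df["snp_id"].isin(nullspecs.keys())]
    if len(missing):
        raise KeyError(f"no NullSpec for snp_id {missing.iloc[0]!r}")
    null_p = df["snp_id"].map(
        lambda s: nullspecs[s].null_p if nullspecs[s].verdict is NullVerdict.TESTABLE else np.nan
    )
    testable = null_p.notna()
    discarded["not_testable"] = int((~testable).sum())
    df = df[testable]
    df["null_p"] = null_p[testable].astype(float)

    if len(df):
        df["p_value"] = binomial_p_values(
            df["g1_count"].to_numpy(), df["g2_count"].to_numpy(), df["null_p"].to_numpy()
        )
        if bh_family == "per_dataset":
            df["q_value"] = df.groupby("dataset_id")["p_value"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        else:
            df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] < alpha
    else:
        df["p_value"] = df["q_value"] = np.empty(0)
        df["significant"] = np.empty(0, dtype=bool)

    as_ids = set(df.loc[df["significant"], "snp_id"])
    return df.reset_index(drop=True), as_ids, discarded
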