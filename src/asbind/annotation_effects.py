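"""Frequency classification, allele-specific effect sizes and summaries.

An AS-SNP is *common* when its population allele frequency is at least 1 %
and *rare* when the frequency is below 1 % or the SNP is absent from the
frequency reference altogether.  The allele-specific effect of a SNP is the
fraction of reads carried by the stronger allele, max(G1,G2)/(G1+G2), which
is 0.5 at perfect balance and approaches 1 for complete imbalance; common
and rare groups are compared with Welch's two-tailed t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COMMON_AF_THRESHOLD = 0.01


@dataclass(frozen=True)
class AnnotatedASSNP:
    """One called AS-SNP in one cell line with its effect summary."""

    snp_id: str
    cell_line: str
    freq_class: str  # "common" | "rare"
    af: Optional[float]
    effect_ratio: float
    best_q: float
    n_supporting_datasets: int
    dataset_ids: tuple[str, ...]


@dataclass(frozen=True)
class CommonRareComparison:
    t_statistic: float
    p_value: float
    common_mean: float
    rare_mean: float
    n_common: int
    n_rare: int


@dataclass(frozen=True)
class SharingResult:
    """Multiplicity histograms of heterozygous and AS-SNPs across cell lines."""

    het_histogram: dict[int, int]
    as_histogram: dict[int, int]
    chi2: float
    p_value: float


def classify_frequency(
    snp_id: str,
    frequency_table: Mapping[str, float],
    common_threshold: float = COMMON_AF_THRESHOLD,
) -> str:
    """Classify as "common" (AF >= threshold) or "rare" (below, or absent)."""
    af = frequency_table.get(snp_id)
    if af is not None and af >= common_threshold:
        return "common"
    return "rare"


def as_effect_ratio(g1: int, g2: int) -> float:
    """Fraction of reads on the stronger allele: max(g1, g2) / (g1 + g2)."""
    if g1 < 1 or g2 < 1:
        raise ValueError(f"both alleles need >= 1 read, got ({g1}, {g2})")
    return max(g1, g2) / (g1 + g2)


def annotate_as_snps(
    results: pd.DataFrame,
    frequency_table: Mapping[str, float],
    cell_line: str,
    common_threshold: float = COMMON_AF_THRESHOLD,
    ratio_from: str = "best_q",
) -> list[AnnotatedASSNP]:
    """Aggregate per-(SNP, dataset) test results to one annotation per AS-SNP.

    The per-SNP effect ratio is taken from a single dataset: the one with the
    smallest q-value (``ratio_from="best_q"``, ties broken by dataset_id) or
    the one with the highest total depth (``ratio_from="max_depth"``).
    """
    if ratio_from not in ("best_q", "max_depth"):
        raise ValueError(f"ratio_from must be best_q or max_depth, got {ratio_from}")
    sig = results[results["significant"]]
    out: list[AnnotatedASSNP] = []
    for snp_id, grp in sig.groupby("snp_id", sort=True):
        grp = grp.sort_values(["q_value", "dataset_id"]) if ratio_from == "best_q" else (
            grp.assign(_depth=grp["g1_count"] + grp["g2_count"]).sort_values(
                ["_depth", "dataset_id"], ascending=[False, True]
            )
        )
        top = grp.iloc[0]
        out.append(
            AnnotatedASSNP(
                snp_id=snp_id,
                cell_line=cell_line,
                freq_class=classify_frequency(snp_id, frequency_table, common_threshold),
                af=frequency_table.get(snp_id),
                effect_ratio=as_effect_ratio(int(top["g1_count"]), int(top["g2_count"])),
                best_q=float(grp["q_value"].min()),
                n_supporting_datasets=len(grp),
                dataset_ids=tuple(sorted(grp["dataset_id"])),
            )
        )
    return out


def annotations_to_frame(annotations: Sequence[AnnotatedASSNP]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.snp_id,
                a.cell_line,
                a.freq_class,
                "" if a.af is None else a.af,
                a.effect_ratio,
                a.best_q,
                a.n_supporting_datasets,
                ",".join(a.dataset_ids),
            )
            for a in annotations
        ],
        columns=[
            "snp_id",
            "cell_line",
            "freq_class",
            "af",
            "effect_ratio",
            "best_q",
            "n_supporting_datasets",
            "dataset_ids",
        ],
    )


def compare_common_rare_effects(
    common_ratios: Sequence[float], rare_ratios: Sequence[float]
) -> CommonRareComparison:
    """Welch's two-tailed t test comparing per-SNP effect ratios."""
    common = np.asarray(common_ratios, dtype=float)
    rare = np.asarray(rare_ratios, dtype=float)
    if len(common) < 2 or len(rare) < 2:
        raise ValueError("each group needs >= 2 effect ratios")
    if np.var(common) == 0 and np.var(rare) == 0:
        raise ValueError("both groups have zero variance; t statistic undefined")
    t, p = stats.ttest_ind(common, rare, equal_var=False)
    return CommonRareComparison(
        t_statistic=float(t),
        p_value=float(p),
        common_mean=float(common.mean()),
        rare_mean=float(rare.mean()),
        n_common=len(common),
        n_rare=len(rare),
    )


def cross_cell_sharing(
    het_sets: Mapping[str, set[str]], as_sets: Mapping[str, set[str]]
) -> SharingResult:
    """Compare how heterozygous SNPs and AS-SNPs distribute across cell lines.

    For each universe, counts SNPs present in exactly 1..k cells, then runs a
    Pearson chi-square on the het-vs-AS contingency table over multiplicity.
    """
    cells = sorted(het_sets)
    for cell in as_sets:
        extra = as_sets[cell] - het_sets.get(cell, set())
        if extra:
            raise ValueError(
                f"AS-SNP {next(iter(extra))!r} not heterozygous in cell {cell!r}"
            )
    k = len(cells)

    def histogram(sets: Mapping[str, set[str]]) -> dict[int, int]:
        mult: dict[str, int] = {}
        for cell in cells:
            for snp in sets.get(cell, set()):
                mult[snp] = mult.get(snp, 0) + 1
        hist = {i: 0 for i in range(1, k + 1)}
        for count in mult.values():
            hist[count] += 1
        return hist

    het_hist = histogram(het_sets)
    as_hist = histogram(as_sets)
    table = np.array(
        [[het_hist[i] for i in range(1, k + 1)], [as_hist[i] for i in range(1, k + 1)]]
    )
    # drop multiplicity columns empty in both universes
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table)
    return SharingResult(het_histogram=het_hist, as_histogram=as_hist, chi2=float(chi2), p_value=float(p))


def tf_detection_coverage(results: pd.DataFrame) -> pd.DataFrame:
    """Rank datasets by AS-SNPs detected and accumulate union coverage.

    Returns one row per dataset, ordered by detection count (ties broken
    lexicographically by dataset_id), with the fraction of all AS-SNPs
    covered by the top-k datasets.  Reproduces the "top 20 TFs" analysis:
    coverage(k) is non-decreasing and reaches 1 at the last dataset.
    """
    sig = results[results["significant"]]
    if sig.empty:
        raise ValueError("no significant results to rank")
    all_as = set(sig["snp_id"])
    per_ds = (
        sig.groupby("dataset_id")["snp_id"]
        .agg(set)
        .reset_index(name="snps")
    )
    per_ds["n_as"] = per_ds["snps"].map(len)
    per_ds = per_ds.sort_values(["n_as", "dataset_id"], ascending=[False, True]).reset_index(drop=True)
    covered: set[str] = set()
    rows = []
    for k, row in enumerate(per_ds.itertuples(index=False), start=1):
        covered |= row.snps
        rows.append((k, row.dataset_id, row.n_as, len(covered) / len(all_as)))
    return pd.DataFrame(rows, columns=["rank", "dataset_id", "n_as_snps", "cumulative_coverage"])
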