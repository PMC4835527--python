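"""Geometric pruning of candidate AS-SNPs with a full removal audit trail.

Candidates are removed when they fall inside flanked assembly-gap regions
(centromeres/telomeres +/- 1 Mb by default), flanked signal-artifact
blacklist regions (+/- 100 bp), or CNV regions that make the binomial null
uninterpretable (ungenotyped, unresolved three-copy, or >= four copies).
Each SNP is removed at most once, attributed to the first matching reason
in that fixed order, so the report reconciles exactly with the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._intervals import PointLookup, merge_intervals
from .as_detection import NullSpec, NullVerdict
from .variant_io import GenomicInterval, HetSNP

#: removal reasons in attribution order
FILTER_REASONS = (
    "gap_flank",
    "blacklist_flank",
    "ungenotyped_cnv",
    "unresolved_cnv",
    "high_copy_cnv",
)

_VERDICT_REASON = {
    NullVerdict.EXCLUDED_UNGENOTYPED_CNV: "ungenotyped_cnv",
    NullVerdict.EXCLUDED_UNRESOLVED_CNV: "unresolved_cnv",
    NullVerdict.EXCLUDED_HIGH_COPY: "high_copy_cnv",
}


@dataclass
class FilterReport:
    input_count: int
    removed_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_REASONS}
    )
    output_count: int = 0

    def reconciles(self) -> bool:
        return self.input_count == self.output_count + sum(self.removed_by_reason.values())


def expand_intervals(
    intervals: Iterable[GenomicInterval],
    flank: int,
    chrom_sizes: Mapping[str, int],
) -> list[GenomicInterval]:
    """Widen each interval by ``flank`` on both sides, clamp to the
    chromosome, and merge the overlaps."""
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    widened = []
    for iv in intervals:
        size = chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        if iv.end > size:
            raise ValueError(f"interval {iv.chrom}:[{iv.start},{iv.end}) beyond length {size}")
        widened.append(
            GenomicInterval(iv.chrom, max(0, iv.start - flank), min(size, iv.end + flank))
        )
    return merge_intervals(widened) if widened else []


def apply_region_filters(
    snps: Sequence[HetSNP],
    gap_intervals: Sequence[GenomicInterval],
    blacklist_intervals: Sequence[GenomicInterval],
    cnv_verdicts: Mapping[str, NullSpec],
) -> tuple[list[HetSNP], FilterReport]:
    """Remove SNPs in masked regions or excluded CNVs.

    ``gap_intervals`` and ``blacklist_intervals`` must already carry their
    flanks (see :func:`expand_intervals`).  Containment is half-open:
    a SNP at exactly ``end`` is retained.
    """
    gaps = PointLookup(gap_intervals)
    blacklist = PointLookup(blacklist_intervals)
    report = FilterReport(input_count=len(snps))
    retained: list[HetSNP] = []
    for snp in snps:
        if gaps.contains(snp.chrom, snp.pos):
            report.removed_by_reason["gap_flank"] += 1
            continue
        if blacklist.contains(snp.chrom, snp.pos):
            report.removed_by_reason["blacklist_flank"] += 1
            continue
        spec = cnv_verdicts.get(snp.snp_id)
        if spec is not None and spec.verdict is not NullVerdict.TESTABLE:
            report.removed_by_reason[_VERDICT_REASON[spec.verdict]] += 1
            continue
        retained.append(snp)
    report.output_count = len(retained)
    return retained, report
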