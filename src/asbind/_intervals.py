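"""Internal interval arithmetic on 0-based half-open coordinates."""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

from .variant_io import GenomicInterval


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals per chromosome; output sorted."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


class PointLookup:
    """Membership queries (pos in any interval) over a merged interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in merge_intervals(intervals) if intervals else []:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]


class RegionLookup:
    """Find which (possibly overlapping) labelled regions cover a point."""

    def __init__(self, regions: Sequence, key=lambda r: r):
        # regions expose .chrom/.start/.end through `key` returning a GenomicInterval
        self._by_chrom: dict[str, list[tuple[int, int, object]]] = {}
        for r in regions:
            iv = key(r)
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, r))
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda t: t[0])

    def overlapping(self, chrom: str, pos: int) -> list:
        hits = []
        for start, end, r in self._by_chrom.get(chrom, []):
            if start > pos:
                break
            if pos < end:
                hits.append(r)
        return hits
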