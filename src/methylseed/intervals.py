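"""Small vectorized interval helpers (0-based half-open throughout)."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["merge_intervals", "IntervalIndex", "total_length", "intersect_length"]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals on one chromosome as a sorted, disjoint list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class IntervalIndex:
    """Per-chromosome merged interval set supporting overlap queries.

    Built from ``(chrom, start, end)`` triples; ``overlaps`` answers whether a
    query interval shares >= 1 bp with the set, vectorized over queries.
    """

    def __init__(self, triples: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def merged(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self._starts:
            return []
        return list(zip(self._starts[chrom].tolist(), self._ends[chrom].tolist()))

    def overlaps(self, chrom, start, end) -> np.ndarray:
        """Boolean array: query i overlaps the set by >= 1 bp.

        ``chrom`` may be a scalar (all queries on one chromosome) or an array
        aligned with ``start``/``end``.
        """
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if isinstance(chrom, str):
            return self._overlaps_one(chrom, start, end)
        chrom = np.asarray(chrom)
        out = np.zeros(len(start), dtype=bool)
        for c in np.unique(chrom):
            m = chrom == c
            out[m] = self._overlaps_one(str(c), start[m], end[m])
        return out

    def _overlaps_one(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        if chrom not in self._starts:
            return np.zeros(len(start), dtype=bool)
        ss, ee = self._starts[chrom], self._ends[chrom]
        # rightmost interval with interval.start < query.end
        idx = np.searchsorted(ss, end, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(start), dtype=bool)
        hit[ok] = ee[idx[ok]] > start[ok]
        return hit

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values())
                       ) if self._starts else 0)

    def intersect_length(self, other: "IntervalIndex") -> int:
        total = 0
        for chrom in self._starts:
            if chrom not in other._starts:
                continue
            a = list(zip(self._starts[chrom], self._ends[chrom]))
            b = list(zip(other._starts[chrom], other._ends[chrom]))
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if e > s:
                    total += int(e - s)
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return total


def total_length(triples: Iterable[tuple[str, int, int]]) -> int:
    """Total base pairs covered by the union of the given intervals."""
    return IntervalIndex(triples).total_length()


def intersect_length(a: Iterable[tuple[str, int, int]], b: Iterable[tuple[str, int, int]]) -> int:
    """Base pairs in the intersection of two interval unions."""
    return IntervalIndex(a).intersect_length(IntervalIndex(b))
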