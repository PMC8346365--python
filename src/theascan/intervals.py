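"""Half-open genomic interval sets and interval arithmetic.

Coordinates are 0-based, half-open ``[start, end)`` throughout, matching BED.
An :class:`IntervalSet` stores, per chromosome, a merged (sorted, disjoint)
representation, so membership queries reduce to a binary search.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge possibly overlapping half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: List[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class IntervalSet:
    """Per-chromosome sets of merged half-open intervals."""

    def __init__(self, intervals: Dict[str, Iterable[Interval]] | None = None):
        self._by_chrom: Dict[str, List[Interval]] = {}
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._set(chrom, merge_intervals(ivs))

    def _set(self, chrom: str, merged: List[Interval]) -> None:
        self._by_chrom[chrom] = merged
        self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
        self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str) -> List[Interval]:
        return list(self._by_chrom.get(chrom, []))

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in self.chroms:
            for s, e in self._by_chrom[chrom]:
                yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 0-based position ``pos`` falls inside any interval."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def contains_many(self, chrom: str, positions: Sequence[int]) -> np.ndarray:
        """Vectorized :meth:`contains` for an array of 0-based positions."""
        pos = np.asarray(positions, dtype=np.int64)
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(pos.shape, dtype=bool)
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = i >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < self._ends[chrom][i[ok]]
        return out

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Whether [start, end) intersects any stored interval."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, end, side="left")) - 1
        return i >= 0 and self._ends[chrom][i] > start


def coverage_lengths(groups: Sequence[IntervalSet]) -> Dict[str, int]:
    """Shared/unique/total accounting over several interval sets.

    Returns a dict with ``shared`` (bp covered by *every* group), ``unique``
    (bp covered by exactly one group), ``total`` (bp covered by at least one),
    and ``per_group`` (list of each group's own total length).  Computed by a
    sweep over breakpoints counting how many groups cover each segment.
    """
    n_groups = len(groups)
    shared = unique = total = 0
    all_chroms = sorted({c for g in groups for c in g.chroms})
    for chrom in all_chroms:
        events: List[Tuple[int, int]] = []
        for g in groups:
            for s, e in g.intervals(chrom):
                events.append((s, +1))
                events.append((e, -1))
        events.sort()
        depth = 0
        prev = None
        for pos, delta in events:
            if prev is not None and pos > prev and depth > 0:
                seg = pos - prev
                total += seg
                if depth == n_groups:
                    shared += seg
                if depth == 1:
                    unique += seg
            depth += delta
            prev = pos
    return {
        "shared": shared,
        "unique": unique,
        "total": total,
        "per_group": [g.total_length() for g in groups],
    }
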