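"""Sliding and tiling genomic windows."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np


@dataclass(frozen=True)
class Window:
    """Half-open genomic window [start, end), 0-based."""

    chrom: str
    start: int
    end: int
    n_sites: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: Dict[str, int], size: int, step: int | None = None) -> List[Window]:
    """Tile each chromosome with sliding windows.

    Windows start at 0, size, ... with the given step (default: ``size``,
    i.e. non-overlapping), each truncated at the chromosome end.  Requires
    ``size >= step >= 1``.
    """
    if step is None:
        step = size
    if not (size >= step >= 1):
        raise ValueError(f"require size >= step >= 1, got size={size} step={step}")
    windows: List[Window] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            windows.append(Window(chrom, start, min(start + size, length)))
            start += step
    return windows


def assign_sites(windows: Sequence[Window], chrom: str, positions: Sequence[int]) -> List[Window]:
    """Count 0-based sites per window; a site p belongs to windows with start <= p < end."""
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    out = []
    for w in windows:
        if w.chrom != chrom:
            out.append(w)
            continue
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="left")
        out.append(Window(w.chrom, w.start, w.end, int(hi - lo)))
    return out


def window_site_slices(windows: Sequence[Window], positions: np.ndarray) -> List[slice]:
    """Per-window slices into a sorted 0-based position array (single chromosome)."""
    pos = np.asarray(positions, dtype=np.int64)
    slices = []
    for w in windows:
        lo = int(np.searchsorted(pos, w.start, side="left"))
        hi = int(np.searchsorted(pos, w.end, side="left"))
        slices.append(slice(lo, hi))
    return slices
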