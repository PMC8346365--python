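"""SNP quality filtering and the sweep-scan mask pre-filter.

Filter rules, applied in a fixed order with the first failing rule
attributed in the tally:

1. ``non_snp``       — not a single-nucleotide substitution
2. ``repeat_mask``   — inside a masked (repeat/TE/NUMT/NUPT) interval
3. ``depth``         — site depth outside [min_depth, max_depth]
4. ``missing``       — missing genotype rate above max_missing
5. ``spacing``       — closer than min_spacing bp to ANY other input
                       variant (both members of a too-close pair fail;
                       the boundary is strict: exactly min_spacing apart
                       survives)
6. ``non_biallelic`` — more than one alternate allele

Depth is the site-level summed depth (INFO DP when present, else the sum
of per-sample DP).  The spacing rule is evaluated against the pre-filter
variant set, which makes the whole filter idempotent.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import IntervalSet
from .io import VariantRecord

RULES = ("non_snp", "repeat_mask", "depth", "missing", "spacing", "non_biallelic")


def filter_snps(
    records: Sequence[VariantRecord],
    repeat_mask: Optional[IntervalSet] = None,
    min_depth: int = 5,
    max_depth: int = 1000,
    max_missing: float = 0.40,
    min_spacing: int = 5,
) -> Tuple[List[VariantRecord], Dict[str, int]]:
    """Apply the six quality rules; returns survivors and a per-rule tally.

    Records must be sorted by (chrom, pos); an unsorted input raises.
    The tally plus the survivor count always sums to the input count.
    """
    records = list(records)
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("input records must be sorted by (chrom, pos)")

    # nearest-neighbour distance among ALL input variants, per chromosome
    too_close = [False] * len(records)
    by_chrom: Dict[str, List[int]] = {}
    for i, r in enumerate(records):
        by_chrom.setdefault(r.chrom, []).append(i)
    for idxs in by_chrom.values():
        for a, b in zip(idxs, idxs[1:]):
            if records[b].pos - records[a].pos < min_spacing:
                too_close[a] = True
                too_close[b] = True

    tally = {rule: 0 for rule in RULES}
    survivors: List[VariantRecord] = []
    for i, r in enumerate(records):
        if not r.is_snp:
            tally["non_snp"] += 1
        elif repeat_mask is not None and repeat_mask.contains(r.chrom, r.pos0):
            tally["repeat_mask"] += 1
        elif r.total_depth is not None and not (min_depth <= r.total_depth <= max_depth):
            tally["depth"] += 1
        elif r.missing_rate() > max_missing:
            tally["missing"] += 1
        elif too_close[i]:
            tally["spacing"] += 1
        elif not r.is_biallelic:
            tally["non_biallelic"] += 1
        else:
            survivors.append(r)
    return survivors, tally


def intersect_vcfs(
    records_a: Iterable[VariantRecord], records_b: Iterable[VariantRecord]
) -> List[VariantRecord]:
    """Optional two-caller pre-step: keep A's records whose
    (chrom, pos, ref, alts) key also appears in B."""
    keys_b = {(r.chrom, r.pos, r.ref, r.alts) for r in records_b}
    return [r for r in records_a if (r.chrom, r.pos, r.ref, r.alts) in keys_b]


def mask_positions(
    positions: Sequence[int], chrom: str, masks: Sequence[IntervalSet]
) -> np.ndarray:
    """Boolean keep-mask for 0-based positions against several masks
    (TE/NUMT/NUPT pre-filter of the sweep scan)."""
    pos = np.asarray(positions, dtype=np.int64)
    drop = np.zeros(len(pos), dtype=bool)
    for m in masks:
        drop |= m.contains_many(chrom, pos)
    return ~drop
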