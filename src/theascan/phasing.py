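"""Switch-error evaluation of an assembly-derived haplotype phasing.

A "true" phased SNP set is built by intersecting two independent
block-phased call sets: within every maximal group of SNPs sharing a
phase block in BOTH inputs, relative phases are compared under the block
orientation that maximizes agreement (block orientations are arbitrary),
agreeing SNPs are kept and disagreeing ones dropped.

A test phasing is then scored per truth block: the orientation (A<->B
relabelling) minimizing mismatches is absorbed, and the remaining
minority mismatches are counted as switched bases.  The reported rate is
switched / compared SNPs, so a globally flipped phasing scores 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Tuple


@dataclass(frozen=True)
class PhasedSnp:
    """One phased heterozygous SNP: which haplotype carries the alternate
    allele (0/1), relative to its block's arbitrary orientation."""

    chrom: str
    pos: int
    block_id: int
    phase: int  # 0 or 1


@dataclass
class SwitchErrorReport:
    n_truth: int
    n_compared: int
    n_switched: int
    n_missing: int                    # truth SNPs absent from the test set
    rate: float                       # n_switched / n_compared
    per_block: Dict[Tuple[str, int], Tuple[int, int]] = field(default_factory=dict)
    tied_blocks: List[Tuple[str, int]] = field(default_factory=list)


def build_truth(
    phasing_1: Sequence[PhasedSnp], phasing_2: Sequence[PhasedSnp]
) -> Tuple[List[PhasedSnp], int]:
    """Consistently phased SNPs across two independent phasings.

    SNPs are grouped by the pair (block in set 1, block in set 2); within a
    group the majority orientation between the two phasings is absorbed and
    SNPs whose relative phase still disagrees are dropped.  Returns the
    truth set (re-blocked by intersection group) and the dropped count.
    """
    by_key_1 = {(s.chrom, s.pos): s for s in phasing_1}
    by_key_2 = {(s.chrom, s.pos): s for s in phasing_2}
    groups: Dict[Tuple[str, int, int], List[Tuple[PhasedSnp, PhasedSnp]]] = {}
    for key, s1 in by_key_1.items():
        s2 = by_key_2.get(key)
        if s2 is not None:
            groups.setdefault((s1.chrom, s1.block_id, s2.block_id), []).append((s1, s2))
    if not groups:
        warnings.warn("no overlapping phase blocks between the two input phasings")
    truth: List[PhasedSnp] = []
    dropped = 0
    for new_block, (gkey, pairs) in enumerate(sorted(groups.items())):
        agree = sum(1 for s1, s2 in pairs if s1.phase == s2.phase)
        flip = agree < len(pairs) - agree  # orientation maximizing agreement
        for s1, s2 in pairs:
            consistent = (s1.phase == s2.phase) != flip
            if consistent:
                truth.append(PhasedSnp(s1.chrom, s1.pos, new_block, s1.phase))
            else:
                dropped += 1
    truth.sort(key=lambda s: (s.chrom, s.pos))
    return truth, dropped


def switch_error(
    truth: Sequence[PhasedSnp], test_phase: Dict[Tuple[str, int], int]
) -> SwitchErrorReport:
    """Count switched bases of a test phasing against a truth set.

    ``test_phase`` maps (chrom, pos) to the haplotype (0 = A, 1 = B) the
    test assembly assigns the alternate allele to.  Per truth block the
    orientation minimizing mismatches is chosen; mismatches under that
    orientation are the switched bases.  Blocks with an exact half/half
    split are flagged (n/2 counted).  Truth SNPs absent from the test set
    are excluded from ``n_compared`` and reported as missing.
    """
    blocks: Dict[Tuple[str, int], List[Tuple[int, int]]] = {}
    n_missing = 0
    for s in truth:
        t = test_phase.get((s.chrom, s.pos))
        if t is None:
            n_missing += 1
            continue
        blocks.setdefault((s.chrom, s.block_id), []).append((s.phase, t))

    n_compared = n_switched = 0
    per_block: Dict[Tuple[str, int], Tuple[int, int]] = {}
    tied: List[Tuple[str, int]] = []
    for bkey, pairs in sorted(blocks.items()):
        mism = sum(1 for p, t in pairs if p != t)
        k = len(pairs)
        sw = min(mism, k - mism)
        if k % 2 == 0 and mism == k // 2:
            tied.append(bkey)
        n_compared += k
        n_switched += sw
        per_block[bkey] = (sw, k)
    rate = n_switched / n_compared if n_compared else math.nan
    return SwitchErrorReport(
        n_truth=len(truth),
        n_compared=n_compared,
        n_switched=n_switched,
        n_missing=n_missing,
        rate=rate,
        per_block=per_block,
        tied_blocks=tied,
    )


def rate_from_counts(n_switched: int, n_compared: int) -> float:
    """Percentage switch-error rate printed to one decimal.

    Half-up rounding applied at two decimals and then at one, the
    conventional re-rounding of a percentage reported first at two
    decimals.  Undefined (ValueError) when n_compared == 0.
    """
    if n_compared <= 0:
        raise ValueError("n_compared must be positive")
    pct = Decimal(100 * n_switched) / Decimal(n_compared)
    two = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(two.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
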