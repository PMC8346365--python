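"""Allelic gene pairing and coding-sequence divergence between haplotypes.

Alleles are paired by reciprocal coordinate overlap on the monoploid
reference (>50% of the shorter gene by default), then scored by global
alignment identity, Levenshtein edit distance, and Nei-Gojobori (1986)
Ka/Ks with Jukes-Cantor correction.  Large-effect differences (start/stop
loss, premature stops, frameshifts) are classified with a strand-aware
codon lookup against the standard genetic code.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
from Bio import Align
from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE.get(codon, "X")


# ---------------------------------------------------------------------------
# pairing

@dataclass
class GeneInterval:
    """A gene projected to monoploid coordinates, with its CDS sequence."""

    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    cds: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AllelePair:
    gene_a: str
    gene_b: str
    overlap_frac: float
    collapsed: bool = False      # byte-identical CDS: a single allele
    identity: float = math.nan
    edit_distance: int = -1
    ka: float = math.nan
    ks: float = math.nan
    ka_ks: float = math.nan      # NaN when ks == 0 (flagged, not 0)
    saturated: bool = False
    large_effect: str = "none"


def pair_alleles(
    genes_a: Sequence[GeneInterval],
    genes_b: Sequence[GeneInterval],
    min_overlap: float = 0.5,
) -> List[AllelePair]:
    """Pair genes across haplotypes by coordinate overlap on the monoploid.

    Candidate pairs need overlap / min(lenA, lenB) > ``min_overlap``;
    one-to-one matching is greedy by greatest overlap fraction.  Pairs with
    byte-identical CDS are flagged ``collapsed`` (counted as one allele).
    Symmetric in its two inputs.
    """
    candidates: List[Tuple[float, int, int]] = []
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            if ga.chrom != gb.chrom:
                continue
            ov = min(ga.end, gb.end) - max(ga.start, gb.start)
            if ov <= 0:
                continue
            frac = ov / min(ga.length, gb.length)
            if frac > min_overlap:
                candidates.append((frac, i, j))
    # greedy: highest overlap first, deterministic tie-break on gene ids
    candidates.sort(key=lambda t: (-t[0], genes_a[t[1]].id, genes_b[t[2]].id))
    used_a: set = set()
    used_b: set = set()
    pairs: List[AllelePair] = []
    for frac, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ga, gb = genes_a[i], genes_b[j]
        collapsed = bool(ga.cds) and ga.cds == gb.cds
        pairs.append(AllelePair(ga.id, gb.id, frac, collapsed=collapsed))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


# ---------------------------------------------------------------------------
# alignment scoring

def _aligner(match: float = 1.0, mismatch: float = -1.0, gap_open: float = -2.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def align_and_score(
    cds_a: str,
    cds_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> Tuple[float, int]:
    """Global-alignment identity and Levenshtein edit distance.

    Identity = unsubstituted (identical, aligned) bases / alignment length,
    where gap columns count toward the length but never as matches.  The
    first (high-road) traceback of the aligner is used, so results are
    deterministic.  Edit distance is computed independently (edlib NW).
    """
    if not cds_a or not cds_b:
        raise ValueError("empty sequence")
    aln = _aligner(match, mismatch, gap_open, gap_extend).align(cds_a, cds_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    identity = matches / len(a_row)
    dist = edlib.align(cds_a, cds_b, mode="NW", task="distance")["editDistance"]
    return identity, int(dist)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks

def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous."""
    aa = translate_codon(codon)
    syn = 0
    for nt in "ACGT":
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1:]
        if translate_codon(alt) == aa:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3)."""
    return sum(_syn_fraction(codon, k) for k in range(3))


def _pathway_counts(c1: str, c2: str) -> Tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all
    substitution orderings between two codons.

    Changes producing or removing a stop codon count as nonsynonymous
    (pathways through stops are not discarded).
    """
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if translate_codon(nxt) == translate_codon(cur):
                syn_tot += 1
            else:
                nonsyn_tot += 1
            cur = nxt
        n_paths += 1
    return syn_tot / n_paths, nonsyn_tot / n_paths


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ka_ks: float       # NaN when ks is 0 or either rate saturated
    S: float           # synonymous sites
    N: float
    Sd: float          # synonymous differences
    Nd: float
    saturated: bool = False
    internal_stop: bool = False


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori pathway counting with Jukes-Cantor correction.

    Requires a gapless codon alignment (equal lengths divisible by 3).
    Codon pairs containing an internal stop flag the result; proportions
    ps or pn >= 0.75 flag saturation (distance undefined).
    """
    if len(cds_a) != len(cds_b) or len(cds_a) % 3 != 0 or not cds_a:
        raise ValueError("sequences must be equal-length, non-empty and codon-aligned")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    internal_stop = False
    n_codons = len(cds_a) // 3
    for i in range(n_codons):
        c1, c2 = cds_a[3 * i: 3 * i + 3], cds_b[3 * i: 3 * i + 3]
        if i < n_codons - 1 and ("*" in (translate_codon(c1), translate_codon(c2))):
            internal_stop = True
        s1, s2 = _codon_sites(c1), _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = not (np.isfinite(ks) and np.isfinite(ka))
    if saturated or ks == 0:
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsResult(ka, ks, ratio, S, N, Sd, Nd, saturated, internal_stop)


# ---------------------------------------------------------------------------
# large-effect variant classification

@dataclass
class GeneModel:
    """Stranded gene model with CDS intervals (0-based half-open, genomic order)."""

    id: str
    chrom: str
    strand: str                      # '+' or '-'
    cds: List[Tuple[int, int]]       # sorted by genomic start

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def _coding_sequence(gene: GeneModel, ref: str) -> str:
    seq = "".join(ref[s:e] for s, e in sorted(gene.cds))
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _coding_offset(gene: GeneModel, pos: int) -> Optional[int]:
    """Offset of genomic position ``pos`` within the spliced CDS (strand-aware)."""
    off = 0
    for s, e in sorted(gene.cds):
        if s <= pos < e:
            plus = off + (pos - s)
            if gene.strand == "+":
                return plus
            return gene.cds_length() - 1 - plus
        off += e - s
    return None


def classify_effect(gene: GeneModel, ref: str, pos: int, ref_allele: str, alt_allele: str) -> str:
    """Classify one variant against one gene model.

    Returns one of: synonymous, nonsynonymous, premature_stop, stop_loss,
    start_loss, splice_site, frameshift_indel, inframe_indel,
    intergenic_intronic.  ``pos`` is 0-based on the reference; the gene's
    CDS length must be divisible by 3 (else ValueError: gene flagged by
    callers, variant skipped).  Splice sites are the 2 bp at either end of
    each intron.
    """
    if gene.cds_length() % 3 != 0:
        raise ValueError(f"gene {gene.id}: CDS length not divisible by 3")
    is_indel = len(ref_allele) != len(alt_allele)
    in_cds = _coding_offset(gene, pos) is not None

    if is_indel:
        if in_cds:
            return "frameshift_indel" if abs(len(ref_allele) - len(alt_allele)) % 3 else "inframe_indel"
        return "intergenic_intronic"

    # splice sites: first/last 2 bp of each intron
    ivs = sorted(gene.cds)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if e1 <= pos < min(e1 + 2, s2) or max(s2 - 2, e1) <= pos < s2:
            return "splice_site"

    if not in_cds:
        return "intergenic_intronic"

    offset = _coding_offset(gene, pos)
    coding = _coding_sequence(gene, ref)
    alt = alt_allele if gene.strand == "+" else str(Seq(alt_allele).reverse_complement())
    codon_i, within = divmod(offset, 3)
    old_codon = coding[3 * codon_i: 3 * codon_i + 3]
    new_codon = old_codon[:within] + alt + old_codon[within + 1:]
    old_aa, new_aa = translate_codon(old_codon), translate_codon(new_codon)

    if codon_i == 0 and old_codon == "ATG" and new_codon != "ATG":
        return "start_loss"
    if old_aa != "*" and new_aa == "*":
        return "premature_stop"
    if old_aa == "*" and new_aa != "*":
        return "stop_loss"
    if old_aa == new_aa:
        return "synonymous"
    return "nonsynonymous"
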