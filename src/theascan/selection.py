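"""Haplotype-based selective-sweep scans.

EHH (extended haplotype homozygosity) measures the decay of haplotype
identity away from a core site; iHH is its trapezoidal integral over
physical distance; XP-EHH is ln(iHH_A / iHH_B), standardized genome-wide,
with large positive values signalling a sweep in population A.  Following
the selscan convention the cross-population statistic pools both core
alleles and integrates both populations over a common span, truncated
where the COMBINED two-population EHH falls below the cutoff.

Candidate sites (top 5% of positive standardized scores, nearest-rank,
ties inclusive) are clustered into regions and retained only when
supported by a lowest-5% Tajima's D window in the putatively selected
population or a top-5% F_ST window between the contrasted populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .diversity import tail_indices
from .windows import Window

MISSING = -1


@dataclass
class EhhDecay:
    """EHH values at increasing distance from a core site, one side at a time."""

    core_index: int
    offsets_left: np.ndarray    # site indices walking left from the core
    ehh_left: np.ndarray
    offsets_right: np.ndarray
    ehh_right: np.ndarray
    n_carriers: int


def _ehh_side(haps: np.ndarray, carriers: np.ndarray, core: int, step: int) -> Tuple[np.ndarray, np.ndarray]:
    """EHH walking from the core in direction ``step`` (+1 right, -1 left).

    At each site the carrier haplotypes are partitioned by identity of the
    stretch from the core to that site; EHH = sum C(n_g, 2) / C(n_c, 2).
    """
    n_c = len(carriers)
    pairs_total = n_c * (n_c - 1) // 2
    group = np.zeros(n_c, dtype=np.int64)  # single group at the core
    idxs, vals = [], []
    j = core + step
    S = haps.shape[1]
    while 0 <= j < S:
        col = haps[carriers, j]
        # refine groups by the allele at site j (missing treated as its own allele)
        key = group * 3 + np.where(col == MISSING, 2, col)
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        ehh = (counts * (counts - 1) // 2).sum() / pairs_total
        idxs.append(j)
        vals.append(ehh)
        if ehh == 0.0:
            break
        j += step
    return np.array(idxs, dtype=np.int64), np.array(vals, dtype=float)


def ehh(haps: np.ndarray, core_index: int, allele: Optional[int] = None) -> EhhDecay:
    """EHH decay around a core site.

    ``allele`` restricts carriers to haplotypes with that allele at the
    core; ``None`` pools all haplotypes (the cross-population convention).
    Requires >= 2 carriers.  EHH is 1 at the core and non-increasing with
    distance on each side.
    """
    haps = np.asarray(haps)
    if allele is None:
        carriers = np.arange(haps.shape[0])
    else:
        carriers = np.flatnonzero(haps[:, core_index] == allele)
    if len(carriers) < 2:
        raise ValueError("EHH requires at least 2 carrier haplotypes")
    li, lv = _ehh_side(haps, carriers, core_index, -1)
    ri, rv = _ehh_side(haps, carriers, core_index, +1)
    return EhhDecay(core_index, li, lv, ri, rv, len(carriers))


def _ihh_side(
    positions: np.ndarray, core: int, idxs: np.ndarray, vals: np.ndarray, cutoff: float
) -> Tuple[float, bool]:
    """Trapezoidal integral of one EHH side until EHH < cutoff.

    Returns (integral in bp, truncated-at-chromosome-end flag).  The final
    trapezoid down to the first sub-cutoff site is included.
    """
    ihh = 0.0
    prev_pos = positions[core]
    prev_ehh = 1.0
    for j, e in zip(idxs, vals):
        ihh += 0.5 * (prev_ehh + e) * abs(int(positions[j]) - int(prev_pos))
        prev_pos, prev_ehh = positions[j], e
        if e < cutoff:
            return ihh, False
    return ihh, True  # ran off the chromosome with EHH still >= cutoff


class _PairRuns:
    """Per-pair maximal runs of identical sites for a haplotype matrix.

    For pooled-core EHH, a haplotype pair still counts toward EHH at site j
    (right of core i) exactly when its run of identical sites containing
    i+1 extends at least to j.  Precomputing, for every pair and site, the
    end and start of that run turns each core's EHH decay into a counting
    problem over pair run boundaries, independent of walk length.
    Missing calls never match.
    """

    def __init__(self, haps: np.ndarray):
        haps = np.asarray(haps)
        n, S = haps.shape
        ii, jj = np.triu_indices(n, k=1)
        self.n_pairs = len(ii)
        eq = (haps[ii] == haps[jj]) & (haps[ii] != MISSING)   # (pairs, S)
        run_end = np.empty((self.n_pairs, S), dtype=np.int64)
        run_start = np.empty((self.n_pairs, S), dtype=np.int64)
        # run_end[:, j]: last index of the True-run containing j (j-1 if eq[:, j] is False)
        run_end[:, S - 1] = np.where(eq[:, S - 1], S - 1, S - 2)
        for j in range(S - 2, -1, -1):
            run_end[:, j] = np.where(eq[:, j], np.where(eq[:, j + 1], run_end[:, j + 1], j), j - 1)
        run_start[:, 0] = np.where(eq[:, 0], 0, 1)
        for j in range(1, S):
            run_start[:, j] = np.where(eq[:, j], np.where(eq[:, j - 1], run_start[:, j - 1], j), j + 1)
        self.run_end = run_end
        self.run_start = run_start
        self.S = S

    def ehh_right(self, core: int, j_stop: int) -> np.ndarray:
        """EHH at sites core+1 .. j_stop (inclusive)."""
        ends = np.sort(self.run_end[:, core + 1])
        j_arr = np.arange(core + 1, j_stop + 1)
        return (self.n_pairs - np.searchsorted(ends, j_arr, side="left")) / self.n_pairs

    def ehh_left(self, core: int, j_stop: int) -> np.ndarray:
        """EHH at sites core-1 .. j_stop (descending, inclusive)."""
        starts = np.sort(self.run_start[:, core - 1])
        j_arr = np.arange(core - 1, j_stop - 1, -1)
        return np.searchsorted(starts, j_arr, side="right") / self.n_pairs

    def stop_right(self, core: int, cutoff: float) -> Tuple[int, bool]:
        """First site index at which EHH < cutoff (or S-1, flagged truncated)."""
        if core == self.S - 1:
            return core, True
        e = self.ehh_right(core, self.S - 1)
        below = np.flatnonzero(e < cutoff)
        if len(below):
            return core + 1 + int(below[0]), False
        return self.S - 1, True

    def stop_left(self, core: int, cutoff: float) -> Tuple[int, bool]:
        if core == 0:
            return core, True
        e = self.ehh_left(core, 0)
        below = np.flatnonzero(e < cutoff)
        if len(below):
            return core - 1 - int(below[0]), False
        return 0, True


def _ihh_between(runs: "_PairRuns", positions: np.ndarray, core: int, j_right: int, j_left: int) -> float:
    """Trapezoidal integral of one population's EHH over a fixed span."""
    total = 0.0
    if j_right > core:
        e = runs.ehh_right(core, j_right)
        pos = positions[core: j_right + 1].astype(float)
        total += float(np.trapezoid(np.concatenate(([1.0], e)), pos))
    if j_left < core:
        e = runs.ehh_left(core, j_left)
        pos = positions[j_left: core + 1][::-1].astype(float)
        total += float(-np.trapezoid(np.concatenate(([1.0], e)), pos))
    return total


@dataclass
class XpehhScore:
    position: int
    ihh_a: float
    ihh_b: float
    raw: float          # ln(ihh_a / ihh_b); NaN when either iHH is 0
    std: float = math.nan
    candidate: bool = False
    truncated: bool = False


def xpehh(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    positions: np.ndarray,
    ehh_cutoff: float = 0.05,
    top_frac: float = 0.05,
) -> List[XpehhScore]:
    """XP-EHH scan over all sites shared by two populations.

    Pooled-core EHH per population, iHH by trapezoidal integration over bp
    truncated at ``ehh_cutoff``, raw score ln(iHH_A/iHH_B), standardized to
    mean 0 / sd 1 over all defined scores.  Candidates are the top
    ``top_frac`` of sites with positive standardized scores (nearest-rank,
    ties inclusive).  Sites whose integral hit a chromosome end before the
    cutoff are kept but flagged ``truncated``.
    """
    haps_a, haps_b = np.asarray(haps_a), np.asarray(haps_b)
    positions = np.asarray(positions, dtype=np.int64)
    runs_a, runs_b = _PairRuns(haps_a), _PairRuns(haps_b)
    runs_ab = _PairRuns(np.concatenate([haps_a, haps_b], axis=0))
    scores: List[XpehhScore] = []
    for i in range(len(positions)):
        # common integration span: where the COMBINED-sample EHH hits the cutoff
        j_right, tr = runs_ab.stop_right(i, ehh_cutoff)
        j_left, tl = runs_ab.stop_left(i, ehh_cutoff)
        ihh_a = _ihh_between(runs_a, positions, i, j_right, j_left)
        ihh_b = _ihh_between(runs_b, positions, i, j_right, j_left)
        raw = math.log(ihh_a / ihh_b) if ihh_a > 0 and ihh_b > 0 else math.nan
        scores.append(XpehhScore(int(positions[i]), ihh_a, ihh_b, raw, truncated=tr or tl))

    raws = np.array([s.raw for s in scores])
    ok = np.isfinite(raws)
    if ok.sum() >= 2 and raws[ok].std() > 0:
        mean, sd = raws[ok].mean(), raws[ok].std()
        for s in scores:
            if np.isfinite(s.raw):
                s.std = (s.raw - mean) / sd
        pos_idx = [i for i, s in enumerate(scores) if np.isfinite(s.std) and s.std > 0]
        if pos_idx:
            flag = tail_indices([scores[i].std for i in pos_idx], top_frac, side="upper")
            for j in flag:
                scores[pos_idx[j]].candidate = True
    return scores


# ---------------------------------------------------------------------------
# consensus sweep regions

@dataclass
class SweepRegion:
    """Candidate sweep interval with Tajima's D / F_ST validation flags."""

    chrom: str
    start: int
    end: int
    sites: List[int]
    tajd_support: bool = False
    fst_support: bool = False
    genes: List[str] = field(default_factory=list)
    contrast: str = ""

    @property
    def retained(self) -> bool:
        return self.tajd_support or self.fst_support


def cluster_sites(chrom: str, positions: Sequence[int], gap: int = 10_000) -> List[SweepRegion]:
    """Cluster candidate sites into regions.

    Each candidate site tags a gap/2 neighbourhood on both sides; regions
    are unions of overlapping neighbourhoods, so two sites at most ``gap``
    apart join one region and sites further apart start a new one.  Region
    bounds therefore extend gap/2 beyond the terminal candidate sites
    (clipped at 0).
    """
    pad = gap // 2
    regions: List[SweepRegion] = []
    for pos in sorted(int(p) for p in positions):
        if regions and pos - regions[-1].sites[-1] <= gap:
            regions[-1].sites.append(pos)
            regions[-1].end = pos + pad + 1
        else:
            regions.append(SweepRegion(chrom, max(0, pos - pad), pos + pad + 1, [pos]))
    return regions


def sweep_consensus(
    chrom: str,
    candidate_positions: Sequence[int],
    tajd_windows: Sequence[Window],
    fst_windows: Sequence[Window],
    gap: int = 10_000,
    genes: Optional[Sequence[Tuple[str, str, int, int]]] = None,
    contrast: str = "",
) -> List[SweepRegion]:
    """The consensus rule for final sweeps.

    ``tajd_windows`` are the lowest-5% Tajima's D windows of the putatively
    selected population; ``fst_windows`` the top-5% F_ST windows of the
    contrast.  A clustered XP-EHH candidate region is retained iff it
    overlaps at least one window from either set.  ``genes`` are
    (id, chrom, start, end) gene models assigned by any overlap with a
    retained region.
    """
    regions = cluster_sites(chrom, candidate_positions, gap=gap)

    def overlaps_any(r: SweepRegion, windows: Sequence[Window]) -> bool:
        return any(w.chrom == r.chrom and w.start < r.end and r.start < w.end for w in windows)

    retained: List[SweepRegion] = []
    for r in regions:
        r.tajd_support = overlaps_any(r, tajd_windows)
        r.fst_support = overlaps_any(r, fst_windows)
        r.contrast = contrast
        if not r.retained:
            continue
        if genes:
            r.genes = [
                gid for gid, gchrom, gs, ge in genes
                if gchrom == r.chrom and gs < r.end and r.start < ge
            ]
        retained.append(r)
    return retained


def contrast_gene_sets(gene_sets: Dict[str, Dict[str, Set[str]]]) -> Dict[str, object]:
    """Set algebra over selected-gene sets per variety and contrast.

    ``gene_sets`` maps variety -> contrast -> set of gene ids (e.g.
    contrasts "early_domestication" and "improvement").  Returns
    per-contrast counts, the per-variety union (all domesticated genes in
    that variety) and the intersection shared across varieties.
    """
    per_contrast = {
        v: {c: len(s) for c, s in contrasts.items()} for v, contrasts in gene_sets.items()
    }
    unions = {v: set().union(*contrasts.values()) if contrasts else set()
              for v, contrasts in gene_sets.items()}
    union_sizes = {v: len(s) for v, s in unions.items()}
    shared: Set[str] = set.intersection(*unions.values()) if unions else set()
    return {
        "per_contrast": per_contrast,
        "union_per_variety": union_sizes,
        "union_ids": {v: sorted(s) for v, s in unions.items()},
        "shared": len(shared),
        "shared_ids": sorted(shared),
    }
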