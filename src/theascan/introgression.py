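"""Introgression statistics: Patterson's D, f3, and windowed modified f_d.

All statistics are frequency-based, computed from derived-allele
frequencies in four populations arranged as (((P1, P2), P3), O), with the
derived allele polarized by the outgroup.  Significance of genome-wide D
and f3 comes from a weighted delete-one block jackknife over contiguous
genomic blocks (Busing et al. 1999), with per-block weights equal to the
number of informative sites.

The windowed modified f_d follows Martin et al. (2015): the denominator
re-computes the ABBA/BABA masses with the higher of p2 and p3 substituted
as the donor frequency, which stabilizes the estimator in small windows.
Windows with negative Patterson's D and f_d > 1 are excluded, and
introgression outliers are called at the 95th percentile of the remaining
distribution (nearest-rank, ties inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .diversity import tail_indices
from .intervals import IntervalSet, coverage_lengths
from .windows import Window, window_site_slices


# ---------------------------------------------------------------------------
# site patterns

def abba_baba_mass(p1, p2, p3, p4) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA pattern masses from derived-allele frequencies."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


# ---------------------------------------------------------------------------
# weighted block jackknife (Busing, Meijer & van der Leeden 1999)

def block_jackknife_se(theta: float, theta_del: np.ndarray, weights: np.ndarray) -> float:
    """Standard error of a statistic via the weighted delete-one jackknife."""
    g = len(theta_del)
    if g < 2:
        return math.nan
    n = weights.sum()
    h = n / weights
    theta_j = g * theta - ((1 - weights / n) * theta_del).sum()
    var = (((h * theta - (h - 1) * theta_del) - theta_j) ** 2 / (h - 1)).sum() / g
    return math.sqrt(var)


@dataclass
class DStatResult:
    """Genome-wide Patterson's D with block-jackknife Z."""

    sum_abba: float
    sum_baba: float
    D: float
    Z: float
    n_blocks: int
    n_sites: int


def patterson_d(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    positions: Optional[np.ndarray] = None,
    block_size: int = 5_000_000,
) -> DStatResult:
    """Patterson's D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA).

    Frequencies must be polarized so the outgroup-defined ancestral allele
    is 0.  The Z score uses a weighted delete-one jackknife over contiguous
    blocks of ``block_size`` bp (weights = informative sites per block).
    D is NaN (flagged) when the total pattern mass is zero.
    """
    abba, baba = abba_baba_mass(p1, p2, p3, p4)
    ok = np.isfinite(abba) & np.isfinite(baba)
    abba, baba = np.where(ok, abba, 0.0), np.where(ok, baba, 0.0)
    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    denom = tot_a + tot_b
    if denom == 0:
        return DStatResult(tot_a, tot_b, math.nan, math.nan, 0, int(ok.sum()))
    D = (tot_a - tot_b) / denom

    Z = math.nan
    n_blocks = 0
    if positions is not None:
        positions = np.asarray(positions, dtype=np.int64)
        block_ids = positions // block_size
        informative = (abba + baba) > 0
        uniq = np.unique(block_ids[informative])
        theta_del, weights = [], []
        for b in uniq:
            keep = block_ids != b
            da, db = abba[keep].sum(), baba[keep].sum()
            if da + db == 0:
                continue
            theta_del.append((da - db) / (da + db))
            weights.append(int((informative & (block_ids == b)).sum()))
        n_blocks = len(theta_del)
        if n_blocks >= 2:
            se = block_jackknife_se(D, np.array(theta_del), np.array(weights, dtype=float))
            Z = D / se if se > 0 else math.nan
    return DStatResult(tot_a, tot_b, D, Z, n_blocks, int(ok.sum()))


# ---------------------------------------------------------------------------
# modified f_d in windows

@dataclass
class FdWindow:
    """One non-overlapping window of the modified f_d scan."""

    window: Window
    n_snps: int
    d: float          # window Patterson's D
    fd: float         # modified f_d (NaN when undefined or excluded)
    s_num: float
    s_den: float
    excluded: bool = False
    outlier: bool = False


def modified_fd(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    p4: np.ndarray,
    positions: np.ndarray,
    windows: Sequence[Window],
) -> List[FdWindow]:
    """Windowed modified f_d.

    Numerator: sum(ABBA - BABA).  Denominator: the same sum with the donor
    frequency p_D = max(p2, p3) substituted for both P2 and P3.  Windows
    with negative Patterson's D and f_d > 1 are excluded (fd set to NaN,
    ``excluded`` flagged); windows with zero denominator are flagged
    undefined the same way but not marked excluded.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba, baba = abba_baba_mass(p1, p2, p3, p4)
    pd_ = np.maximum(p2, p3)
    abba_d = (1 - p1) * pd_ * pd_ * (1 - p4)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - p4)
    num_site = abba - baba
    den_site = abba_d - baba_d
    informative = np.isfinite(num_site) & np.isfinite(den_site)

    out: List[FdWindow] = []
    for w, sl in zip(windows, window_site_slices(windows, positions)):
        ok = informative[sl]
        n_snps = int(ok.sum())
        a, b = abba[sl][ok].sum(), baba[sl][ok].sum()
        d = (a - b) / (a + b) if (a + b) > 0 else math.nan
        s_num = float(num_site[sl][ok].sum())
        s_den = float(den_site[sl][ok].sum())
        fd = s_num / s_den if s_den != 0 else math.nan
        excluded = bool(np.isfinite(d) and np.isfinite(fd) and d < 0 and fd > 1)
        if excluded:
            fd = math.nan
        out.append(FdWindow(w, n_snps, d, fd, s_num, s_den, excluded))
    return out


def fd_outliers(fd_windows: Sequence[FdWindow], percentile: float = 95.0, min_windows: int = 20) -> List[FdWindow]:
    """Flag introgression outliers at the upper tail of the f_d distribution.

    The threshold is the nearest-rank (100 - percentile)% upper tail over
    non-excluded, defined windows, ties inclusive; excluded windows are
    never outliers.  Returns the input list with ``outlier`` flags set.
    """
    usable = [i for i, fw in enumerate(fd_windows) if not fw.excluded and np.isfinite(fw.fd)]
    if len(usable) < min_windows:
        raise ValueError(f"need >= {min_windows} non-excluded windows, have {len(usable)}")
    vals = [fd_windows[i].fd for i in usable]
    flag = tail_indices(vals, 1.0 - percentile / 100.0, side="upper")
    flagged = {usable[j] for j in flag}
    for i, fw in enumerate(fd_windows):
        fw.outlier = i in flagged
    return list(fd_windows)


# ---------------------------------------------------------------------------
# f3 admixture test

@dataclass
class F3Result:
    """f3(C; A, B) with jackknife SE and (optionally BH-adjusted) Z."""

    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    adj_z: float = math.nan
    label: str = ""


def f3_test(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    n_c: Optional[np.ndarray] = None,
    positions: Optional[np.ndarray] = None,
    block_size: int = 5_000_000,
    bias_correction: bool = True,
) -> F3Result:
    """Three-population test f3(C; A, B) = E[(c - a)(c - b)].

    A significantly negative f3 indicates the target C is admixed between
    sources related to A and B.  The within-C sampling-bias correction
    c(1-c)/(n_c - 1) is subtracted per site when allele counts ``n_c`` are
    supplied (and >= 2).  SE via weighted delete-one block jackknife.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    prod = (c - a) * (c - b)
    if bias_correction and n_c is not None:
        n_c = np.asarray(n_c, dtype=float)
        corr = np.where(n_c >= 2, c * (1 - c) / np.maximum(n_c - 1, 1e-300), 0.0)
        prod = prod - corr
    ok = np.isfinite(prod)
    if not ok.any():
        return F3Result(math.nan, math.nan, math.nan, 0, 0)
    f3 = float(prod[ok].mean())

    se = z = math.nan
    n_blocks = 0
    if positions is not None:
        positions = np.asarray(positions, dtype=np.int64)
        block_ids = positions // block_size
        uniq = np.unique(block_ids[ok])
        theta_del, weights = [], []
        for blk in uniq:
            keep = ok & (block_ids != blk)
            if keep.sum() == 0:
                continue
            theta_del.append(float(prod[keep].mean()))
            weights.append(int((ok & (block_ids == blk)).sum()))
        n_blocks = len(theta_del)
        if n_blocks >= 2:
            se = block_jackknife_se(f3, np.array(theta_del), np.array(weights, dtype=float))
            z = f3 / se if se > 0 else math.nan
    return F3Result(f3, se, z, n_blocks, int(ok.sum()))


def adjust_z(results: Sequence[F3Result]) -> List[F3Result]:
    """Benjamini-Hochberg adjustment of f3 Z scores across a batch of tests.

    One-sided p = Phi(z) (small when z is very negative), BH-adjusted over
    the batch, then mapped back to an adjusted Z = Phi^-1(p_adj).  Monotone
    and rank-preserving; significance is called at adj_z < -1.96.  NaN Z
    scores are passed through unadjusted.
    """
    from statsmodels.stats.multitest import multipletests

    idx = [i for i, r in enumerate(results) if np.isfinite(r.z)]
    if idx:
        p = norm.cdf([results[i].z for i in idx])
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        p_adj = np.clip(p_adj, 1e-300, 1.0 - 1e-16)
        for i, pa in zip(idx, p_adj):
            results[i].adj_z = float(norm.ppf(pa))
    return list(results)


# ---------------------------------------------------------------------------
# shared / unique introgressed-interval accounting

def region_accounting(groups: Dict[str, IntervalSet]) -> Dict[str, object]:
    """Shared (all groups), unique (exactly one) and total introgressed bp.

    Order-independent interval arithmetic over the union of all groups'
    outlier windows.
    """
    names = list(groups)
    res = coverage_lengths([groups[n] for n in names])
    return {
        "shared": res["shared"],
        "unique": res["unique"],
        "total": res["total"],
        "per_group": dict(zip(names, res["per_group"])),
    }
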