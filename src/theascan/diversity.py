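"""Diversity and differentiation statistics.

Implements the classic frequency-based estimators on called genotypes:
per-site nucleotide diversity (mean pairwise difference), Watterson's
theta, Tajima's D, the Weir & Cockerham (1984) F_ST variance-component
estimator (with Hudson's estimator as a secondary output), the folded
site-frequency spectrum, and r-squared LD decay with the half-decay
distance.

Conventions
-----------
Haplotype matrices are (n_haplotypes x n_sites) int8 arrays with alleles
coded 0/1 and missing as -1.  Diploid genotype matrices are
(n_samples x n_sites) dosage arrays with values 0/1/2 and missing -1.
Windowed statistics report both the window sum and the per-bp value
(sum divided by window length, the VCFtools convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .windows import Window, window_site_slices

MISSING = -1


@dataclass(frozen=True)
class TajimaConstants:
    """Sample-size constants of Tajima's D (Tajima 1989)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def site_pi(p: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """Unbiased per-site mean pairwise difference: 2p(1-p) * n/(n-1).

    ``p`` is the (derived or alternate) allele frequency, ``n`` the number of
    non-missing chromosomes.  Undefined (NaN) when n < 2.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n >= 2, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1e-300), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating sites and summed per-site pi.

    Returns NaN (undefined) when S == 0; callers must exclude such
    windows from percentile ranking rather than treating them as 0.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 sequences")
    if S == 0:
        return math.nan
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_sum - S / c.a1) / math.sqrt(var)


def haplotype_freqs(haps: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequency and non-missing chromosome count."""
    haps = np.asarray(haps)
    called = haps != MISSING
    n = called.sum(axis=0).astype(float)
    cnt = np.where(called, haps, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, cnt / np.maximum(n, 1e-300), np.nan)
    return p, n


def genotype_freqs(geno: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site allele frequency, diploid sample count, observed het fraction."""
    geno = np.asarray(geno)
    called = geno != MISSING
    n = called.sum(axis=0).astype(float)
    dos = np.where(called, geno, 0).sum(axis=0).astype(float)
    het = ((geno == 1) & called).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dos / np.maximum(2.0 * n, 1e-300), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1e-300), np.nan)
    return p, n, h


def wc_fst_components(genos: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components a, b, c.

    ``genos`` holds one diploid dosage matrix per population.  Components
    follow the diploid estimator with observed heterozygosity; per-site
    values may be negative.  Sites where any population has < 2 called
    samples, or n_c <= 0, are returned as NaN.
    """
    r = len(genos)
    if r < 2:
        raise ValueError("need at least two populations")
    stats = [genotype_freqs(g) for g in genos]
    p_i = np.stack([s[0] for s in stats])       # (r, S)
    n_i = np.stack([s[1] for s in stats])
    h_i = np.stack([s[2] for s in stats])

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_tot = r * n_bar
        n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = (n_i < 2).any(axis=0) | ~np.isfinite(n_c) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(genos: Sequence[np.ndarray]) -> float:
    """Ratio-of-sums Weir-Cockerham F_ST over all (defined) sites.

    NaN when no site contributes variance (e.g. a monomorphic window).
    """
    a, b, c = wc_fst_components(genos)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if not ok.any() or denom == 0:
        return math.nan
    return float(a[ok].sum() / denom)


def hudson_fst(p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray) -> float:
    """Hudson's F_ST (ratio of sums) from haplotype-level frequencies.

    Secondary estimator used for cross-checks against the Weir-Cockerham
    diploid estimator.
    """
    p1, n1, p2, n2 = (np.asarray(x, dtype=float) for x in (p1, n1, p2, n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1e-300) - p2 * (1 - p2) / np.maximum(n2 - 1, 1e-300)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (n1 >= 2) & (n2 >= 2)
    if not ok.any() or den[ok].sum() == 0:
        return math.nan
    return float(num[ok].sum() / den[ok].sum())


def folded_sfs(haps: np.ndarray) -> np.ndarray:
    """Folded site-frequency spectrum over minor-allele counts.

    Returns counts for bins 1 .. floor(n/2) (index 0 = singletons/fold of
    (n-1)-tons).  Sites that are monomorphic or contain missing calls with
    fewer than 2 called chromosomes are ignored; the bin sum equals the
    number of polymorphic sites counted.
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    called = haps != MISSING
    nc = called.sum(axis=0)
    dac = np.where(called, haps, 0).sum(axis=0)
    # fold against the per-site called count
    mac = np.minimum(dac, nc - dac)
    nbins = n // 2
    sfs = np.zeros(nbins, dtype=np.int64)
    poly = (mac >= 1) & (nc >= 2)
    for m in mac[poly]:
        # clip for odd per-site call counts folding above n//2
        sfs[min(int(m), nbins) - 1] += 1
    return sfs


def ld_r2_decay(
    haps: np.ndarray,
    positions: np.ndarray,
    max_dist: int,
    bin_size: int,
    max_pairs: int | None = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, Optional[float]]:
    """Mean r-squared per distance bin and the half-decay distance.

    r^2 is the squared Pearson correlation between 0/1 allele indicators of
    a site pair, computed on phased haplotypes.  The half-decay distance is
    the midpoint of the first bin whose mean r^2 drops to at most half of
    the maximum bin mean; ``None`` when the curve never reaches half.
    ``max_pairs`` optionally subsamples site pairs for large inputs.
    """
    haps = np.asarray(haps, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    S = haps.shape[1]
    if S < 2:
        raise ValueError("need at least two segregating sites")
    pairs = [
        (i, j)
        for i in range(S)
        for j in range(i + 1, S)
        if 0 < positions[j] - positions[i] <= max_dist
    ]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng()
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in idx]
    nbins = max_dist // bin_size + (1 if max_dist % bin_size else 0)
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for i, j in pairs:
        x, y = haps[:, i], haps[:, j]
        ok = (x != MISSING) & (y != MISSING)
        x, y = x[ok], y[ok]
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        b = (positions[j] - positions[i] - 1) // bin_size
        sums[b] += r * r
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = np.arange(nbins) * bin_size + bin_size / 2.0
    half_decay: Optional[float] = None
    if np.isfinite(means).any():
        half = np.nanmax(means) / 2.0
        for b in range(nbins):
            if counts[b] > 0 and means[b] <= half:
                half_decay = float(mids[b])
                break
    return mids, means, half_decay


@dataclass
class WindowDiversity:
    """Windowed diversity summary: S, pi, Watterson's theta, Tajima's D, F_ST."""

    window: Window
    S: int
    pi: float                # window sum of per-site pi
    pi_per_bp: float         # pi / window length
    theta_w: float           # S / a1
    tajd: float              # NaN when undefined (S == 0)
    fst: float = math.nan    # optional Weir-Cockerham estimate
    n_eff: float = math.nan  # mean non-missing chromosomes at counted sites


def window_diversity(
    haps: np.ndarray,
    positions: np.ndarray,
    windows: Sequence[Window],
    genos_by_pop: Optional[Sequence[np.ndarray]] = None,
) -> List[WindowDiversity]:
    """Per-window S, pi, theta_W, Tajima's D (and F_ST when two+ pops given).

    ``haps`` and ``positions`` describe one chromosome; ``genos_by_pop``
    optionally provides diploid dosage matrices (same site columns) for a
    windowed Weir-Cockerham F_ST.
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    p, nchrom = haplotype_freqs(haps)
    seg = (p > 0) & (p < 1) & (nchrom >= 2)
    pi_site = np.where(seg, np.nan_to_num(site_pi(p, nchrom)), 0.0)
    consts = tajima_constants(n)
    out: List[WindowDiversity] = []
    for w, sl in zip(windows, window_site_slices(windows, positions)):
        segm = seg[sl]
        S = int(segm.sum())
        pi_sum = float(pi_site[sl].sum())
        theta = S / consts.a1
        tajd = tajimas_d(S, pi_sum, n) if n >= 4 else math.nan
        fst = math.nan
        if genos_by_pop is not None:
            sub = [g[:, sl] for g in genos_by_pop]
            fst = wc_fst(sub)
        n_eff = float(nchrom[sl][segm].mean()) if S else math.nan
        out.append(
            WindowDiversity(w, S, pi_sum, pi_sum / w.length, theta, tajd, fst, n_eff)
        )
    return out


def tail_indices(values: Sequence[float], frac: float, side: str) -> np.ndarray:
    """Indices of the extreme ``frac`` tail among *defined* values, ties inclusive.

    ``side`` is "upper" or "lower".  The threshold is the k-th most extreme
    defined value with k = ceil(frac * m) (nearest-rank); all values at least
    as extreme as the threshold are flagged.  NaNs are never flagged.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    m = int(ok.sum())
    if m == 0:
        return np.zeros(0, dtype=np.int64)
    k = max(1, math.ceil(frac * m - 1e-9))  # guard float noise in frac * m
    defined = v[ok]
    if side == "upper":
        thr = np.sort(defined)[-k]
        mask = ok & (v >= thr)
    elif side == "lower":
        thr = np.sort(defined)[k - 1]
        mask = ok & (v <= thr)
    else:
        raise ValueError("side must be 'upper' or 'lower'")
    return np.flatnonzero(mask)
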