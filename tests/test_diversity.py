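"""Diversity statistics against brute-force oracles.

Every estimator here is checked against an independent implementation
written directly from the textbook formulas (pairwise enumeration for pi,
Tajima 1989 constants, Weir & Cockerham 1984 component algebra).
"""

import itertools
import math

import numpy as np
import pytest

from theascan.diversity import (
    folded_sfs,
    haplotype_freqs,
    hudson_fst,
    ld_r2_decay,
    site_pi,
    tail_indices,
    tajima_constants,
    tajimas_d,
    wc_fst,
    wc_fst_components,
    window_diversity,
)
from theascan.windows import make_windows


# ---------------------------------------------------------------------------
# independent oracles

def pi_bruteforce(alleles):
    """Fraction of differing pairs, enumerated."""
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs) * 1.0


def wc_fst_bruteforce(genos):
    """Weir & Cockerham 1984 from explicit per-site loops."""
    r = len(genos)
    S = genos[0].shape[1]
    num = den = 0.0
    for s in range(S):
        n = [float((g[:, s] >= 0).sum()) for g in genos]
        if any(ni < 2 for ni in n):
            continue
        p = [g[:, s][g[:, s] >= 0].sum() / (2 * ni) for g, ni in zip(genos, n)]
        h = [float((g[:, s] == 1).sum()) / ni for g, ni in zip(genos, n)]
        nbar = sum(n) / r
        nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
        a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestSitePi:
    @pytest.mark.parametrize(
        "alleles,expected",
        [([0, 0, 1, 1], 2 / 3), ([0, 0, 0, 0], 0.0), ([0, 1], 1.0)],
    )
    def test_worked_examples(self, alleles, expected):
        p = np.mean(alleles)
        assert site_pi(p, len(alleles)) == pytest.approx(expected, abs=1e-12)

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            alleles = rng.integers(0, 2, size=n)
            p = alleles.mean()
            assert site_pi(p, n) == pytest.approx(pi_bruteforce(alleles), abs=1e-12)

    def test_undefined_below_two_chromosomes(self):
        assert math.isnan(site_pi(0.0, 1))


class TestTajimasD:
    def test_single_site_worked_example(self):
        # n=4, S=1, p=0.5: pi_sum = 2/3, a1 = 1 + 1/2 + 1/3
        c = tajima_constants(4)
        assert c.a1 == pytest.approx(11 / 6, abs=1e-12)
        d = tajimas_d(1, 2 / 3, 4)
        expected = (2 / 3 - 1 / c.a1) / math.sqrt(c.e1 * 1)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(1.633, abs=2e-3)

    def test_zero_when_pi_equals_watterson(self):
        c = tajima_constants(10)
        assert tajimas_d(5, 5 / c.a1, 10) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_for_no_segregating_sites(self):
        assert math.isnan(tajimas_d(0, 0.0, 10))

    def test_constants_positive_and_a1_increasing(self):
        prev = 0.0
        for n in range(4, 60, 7):
            c = tajima_constants(n)
            assert all(x > 0 for x in (c.a1, c.a2, c.b1, c.b2, c.c1, c.c2, c.e1, c.e2))
            assert c.a1 > prev
            prev = c.a1


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        g1 = np.zeros((4, 3), dtype=np.int8)
        g2 = np.full((5, 3), 2, dtype=np.int8)
        assert wc_fst([g1, g2]) == pytest.approx(1.0, abs=1e-12)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(8, 100)).astype(np.int8)
        est = wc_fst([g, g.copy()])
        assert est <= 0.05

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            genos = [
                np.array([[min(2, max(0, rng.integers(0, 3))) for _ in range(10)] for _ in range(4)], dtype=np.int8)
                for _ in range(2)
            ]
            if not np.isfinite(wc_fst(genos)):
                continue
            assert wc_fst(genos) == pytest.approx(wc_fst_bruteforce(genos), abs=1e-12)

    def test_monomorphic_window_undefined(self):
        g1 = np.zeros((4, 5), dtype=np.int8)
        g2 = np.zeros((4, 5), dtype=np.int8)
        assert math.isnan(wc_fst([g1, g2]))

    def test_hudson_agrees_in_sign_on_diverged_pops(self):
        rng = np.random.default_rng(11)
        h1 = (rng.random((20, 50)) < 0.1).astype(np.int8)
        h2 = (rng.random((20, 50)) < 0.6).astype(np.int8)
        p1, n1 = haplotype_freqs(h1)
        p2, n2 = haplotype_freqs(h2)
        assert hudson_fst(p1, n1, p2, n2) > 0.2


class TestFoldedSfs:
    def test_fold_examples(self):
        sfs = folded_sfs(np.array([[0], [0], [1], [1]], dtype=np.int8))
        assert sfs.tolist() == [0, 1]
        sfs = folded_sfs(np.array([[0], [1], [1], [1]], dtype=np.int8))
        assert sfs.tolist() == [1, 0]

    def test_conserves_segregating_sites(self):
        rng = np.random.default_rng(5)
        haps = (rng.random((12, 200)) < rng.uniform(0.0, 1.0, 200)).astype(np.int8)
        p = haps.mean(axis=0)
        S = int(((p > 0) & (p < 1)).sum())
        assert folded_sfs(haps).sum() == S


class TestLdDecay:
    def test_duplicated_site_r2_one(self):
        rng = np.random.default_rng(1)
        col = (rng.random(20) < 0.5).astype(np.int8)
        haps = np.column_stack([col, col])
        _, means, _ = ld_r2_decay(haps, np.array([0, 100]), max_dist=1000, bin_size=1000)
        assert means[0] == pytest.approx(1.0, abs=1e-12)

    def test_balanced_haplotypes_r2_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 3, dtype=np.int8)
        _, means, _ = ld_r2_decay(haps, np.array([0, 50]), max_dist=100, bin_size=100)
        assert means[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_ld_has_no_half_decay(self):
        col = np.array([0] * 5 + [1] * 5, dtype=np.int8)
        haps = np.column_stack([col] * 4)
        _, _, half = ld_r2_decay(haps, np.array([0, 10, 20, 30]), max_dist=100, bin_size=10)
        assert half is None


class TestTails:
    def test_nearest_rank_upper_tail(self):
        vals = [0.01 * k for k in range(1, 101)]
        idx = tail_indices(vals, 0.05, "upper")
        assert sorted(np.array(vals)[idx]) == pytest.approx([0.96, 0.97, 0.98, 0.99, 1.00])

    def test_all_equal_flags_all(self):
        idx = tail_indices([1.0] * 30, 0.05, "upper")
        assert len(idx) == 30

    def test_nans_never_flagged(self):
        vals = [math.nan, 1.0, 2.0, 3.0, math.nan]
        idx = tail_indices(vals, 0.2, "lower")
        assert set(idx) == {1}


def test_window_diversity_partitions_sites():
    rng = np.random.default_rng(9)
    haps = (rng.random((10, 300)) < 0.3).astype(np.int8)
    positions = np.sort(rng.choice(50_000, 300, replace=False))
    wins = make_windows({"chr1": 50_000}, 10_000, 10_000)
    stats = window_diversity(haps, positions, wins)
    p = haps.mean(axis=0)
    S_total = int(((p > 0) & (p < 1)).sum())
    assert sum(d.S for d in stats) == S_total
    for d in stats:
        assert d.pi >= 0
        assert d.pi_per_bp == pytest.approx(d.pi / d.window.length)
        if d.S == 0:
            assert math.isnan(d.tajd)
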