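"""Allele pairing, alignment scoring, NG86 Ka/Ks and effect classification."""

import itertools
import math

import numpy as np
import pytest

from theascan.alleles import (
    CODON_TABLE,
    GeneInterval,
    GeneModel,
    align_and_score,
    classify_effect,
    ng86_kaks,
    pair_alleles,
    translate_codon,
)


# ---------------------------------------------------------------------------
# independent NG86 oracle (pathway enumeration, structured differently)

def ng86_oracle(s1, s2):
    def syn_sites(codon):
        aa = translate_codon(codon)
        total = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt != codon[pos]:
                    alt = codon[:pos] + nt + codon[pos + 1:]
                    total += (translate_codon(alt) == aa) / 3.0
        return total

    S = N = Sd = Nd = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        ss = (syn_sites(c1) + syn_sites(c2)) / 2
        S += ss
        N += 3 - ss
        diffs = [k for k in range(3) if c1[k] != c2[k]]
        if diffs:
            sd_paths, nd_paths, n_paths = 0, 0, 0
            for order in itertools.permutations(diffs):
                cur = c1
                for k in order:
                    new = cur[:k] + c2[k] + cur[k + 1:]
                    if translate_codon(new) == translate_codon(cur):
                        sd_paths += 1
                    else:
                        nd_paths += 1
                    cur = new
                n_paths += 1
            Sd += sd_paths / n_paths
            Nd += nd_paths / n_paths
    ps, pn = Sd / S, Nd / N
    jc = lambda p: float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(pn), jc(ps)


class TestPairAlleles:
    def test_nested_interval_full_overlap(self):
        a = [GeneInterval("a1", "c", 1000, 2000)]
        b = [GeneInterval("b1", "c", 1100, 1900)]
        (pair,) = pair_alleles(a, b)
        assert pair.overlap_frac == pytest.approx(1.0)

    def test_disjoint_unpaired(self):
        a = [GeneInterval("a1", "c", 0, 100)]
        b = [GeneInterval("b1", "c", 200, 300)]
        assert pair_alleles(a, b) == []

    def test_identical_cds_collapsed(self):
        a = [GeneInterval("a1", "c", 0, 100, cds="ATGAAATAG")]
        b = [GeneInterval("b1", "c", 10, 110, cds="ATGAAATAG")]
        (pair,) = pair_alleles(a, b)
        assert pair.collapsed

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a = [GeneInterval(f"a{i}", "c", int(s), int(s) + int(l))
             for i, (s, l) in enumerate(zip(rng.integers(0, 10_000, 8), rng.integers(200, 900, 8)))]
        b = [GeneInterval(f"b{i}", "c", int(s), int(s) + int(l))
             for i, (s, l) in enumerate(zip(rng.integers(0, 10_000, 8), rng.integers(200, 900, 8)))]
        ab = {(p.gene_a, p.gene_b) for p in pair_alleles(a, b)}
        ba = {(p.gene_b, p.gene_a) for p in pair_alleles(b, a)}
        assert ab == ba

    def test_one_to_one_greedy_by_overlap(self):
        a = [GeneInterval("a1", "c", 0, 1000)]
        b = [GeneInterval("b1", "c", 0, 1000), GeneInterval("b2", "c", 400, 1400)]
        (pair,) = pair_alleles(a, b)
        assert pair.gene_b == "b1"


class TestAlignAndScore:
    def test_identical(self):
        identity, dist = align_and_score("ACGTACGT", "ACGTACGT")
        assert identity == 1.0 and dist == 0

    def test_single_substitution(self):
        identity, dist = align_and_score("ACGT", "ACCT")
        assert identity == pytest.approx(0.75)
        assert dist == 1

    def test_gap_column_counts_against_identity(self):
        identity, dist = align_and_score("ACGT", "ACG")
        assert identity == pytest.approx(0.75)
        assert dist == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_and_score("", "ACGT")


class TestNg86:
    def test_identical_cds_zero_rates(self):
        res = ng86_kaks("ATGAAATTT", "ATGAAATTT")
        assert res.ka == 0.0 and res.ks == 0.0
        assert math.isnan(res.ka_ks)

    def test_glycine_synonymous_worked_example(self):
        res = ng86_kaks("GGGGGG", "GGAGGG")
        assert res.S == pytest.approx(2.0)
        assert res.N == pytest.approx(4.0)
        assert res.Sd == pytest.approx(1.0) and res.Nd == pytest.approx(0.0)
        assert res.ks == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.5), abs=1e-4)
        assert res.ks == pytest.approx(0.8239, abs=1e-4)
        assert res.ka == 0.0 and res.ka_ks == 0.0

    def test_matches_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        bases = "ACGT"
        for _ in range(25):
            n_codons = int(rng.integers(3, 20))
            s1 = "".join(rng.choice(list(bases), 3 * n_codons))
            s2 = list(s1)
            for k in rng.choice(len(s2), size=max(1, len(s2) // 10), replace=False):
                s2[k] = bases[int(rng.integers(4))]
            s2 = "".join(s2)
            res = ng86_kaks(s1, s2)
            ka_o, ks_o = ng86_oracle(s1, s2)
            if res.saturated:
                continue
            assert res.ka == pytest.approx(ka_o, abs=1e-9)
            assert res.ks == pytest.approx(ks_o, abs=1e-9)

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError):
            ng86_kaks("ATGAA", "ATGAAA")


class TestClassifyEffect:
    REF = "NN" + "ATGAAATAG" + "NNNN"   # CDS at [2, 11) on the + strand

    def _gene(self, strand="+"):
        return GeneModel("g1", "c", strand, [(2, 11)])

    def test_premature_stop(self):
        # codon 2 AAA -> TAA
        assert classify_effect(self._gene(), self.REF, 5, "A", "T") == "premature_stop"

    def test_synonymous_lysine(self):
        # codon 2 AAA -> AAG
        assert classify_effect(self._gene(), self.REF, 7, "A", "G") == "synonymous"

    def test_frameshift_insertion(self):
        assert classify_effect(self._gene(), self.REF, 6, "A", "AT") == "frameshift_indel"

    def test_inframe_deletion(self):
        assert classify_effect(self._gene(), self.REF, 5, "AAAT", "A") == "inframe_indel"

    def test_start_loss(self):
        assert classify_effect(self._gene(), self.REF, 2, "A", "G") == "start_loss"

    def test_stop_loss(self):
        assert classify_effect(self._gene(), self.REF, 8, "T", "C") == "stop_loss"

    def test_splice_site_and_intronic(self):
        gene = GeneModel("g2", "c", "+", [(0, 6), (12, 18)])
        ref = "ATGAAA" + "GTXXAG" + "AAATAG"
        assert classify_effect(gene, ref, 6, "G", "A") == "splice_site"
        assert classify_effect(gene, ref, 7, "T", "A") == "splice_site"
        assert classify_effect(gene, ref, 10, "A", "T") == "splice_site"
        assert classify_effect(gene, ref, 11, "G", "T") == "splice_site"
        assert classify_effect(gene, ref, 8, "X", "A") == "intergenic_intronic"

    def test_minus_strand_lookup(self):
        # reverse complement of ATG AAA TAG laid on the minus strand
        from Bio.Seq import Seq

        cds_plus = "ATGAAATAG"
        ref = "NN" + str(Seq(cds_plus).reverse_complement()) + "NN"
        gene = GeneModel("g3", "c", "-", [(2, 11)])
        # genomic position of codon2 position0 (A on + sense) is ref index 2+3..5 reversed:
        # mutate the base pairing with AAA->TAA on the coding strand
        pos = 7  # pairs with coding offset 3 (first base of codon 2)
        assert classify_effect(gene, ref, pos, ref[pos], "A") == "premature_stop"

    def test_all_single_base_changes_partition_by_genetic_code(self):
        """Exhaustive: every mutation of every codon in a 64-codon CDS."""
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=4 - 1) ]
        assert len(codons) == 64
        body = "".join(codons)
        cds = "ATG" + body + "TAG"
        ref = cds
        gene = GeneModel("gx", "c", "+", [(0, len(cds))])
        for ci, codon in enumerate(codons):
            for within in range(3):
                pos = 3 + 3 * ci + within
                for nt in "ACGT":
                    if nt == cds[pos]:
                        continue
                    new_codon = codon[:within] + nt + codon[within + 1:]
                    old_aa, new_aa = translate_codon(codon), translate_codon(new_codon)
                    got = classify_effect(gene, ref, pos, cds[pos], nt)
                    if old_aa == new_aa:
                        assert got == "synonymous"
                    elif old_aa != "*" and new_aa == "*":
                        assert got == "premature_stop"
                    elif old_aa == "*" and new_aa != "*":
                        assert got == "stop_loss"
                    else:
                        assert got == "nonsynonymous"

    def test_cds_not_multiple_of_three_flagged(self):
        gene = GeneModel("gb", "c", "+", [(0, 4)])
        with pytest.raises(ValueError):
            classify_effect(gene, "ATGAA", 1, "T", "C")
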