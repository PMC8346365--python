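"""Wright-Fisher simulator: determinism, equilibrium diversity, demography.

The coalescent expectation E[pi] = 4*N*mu per site is checked both
against theory and against an independent coalescent simulator
(msprime) run at the same scaled parameters.
"""

import numpy as np
import pytest
from scipy import stats

from theascan.diversity import folded_sfs, haplotype_freqs, site_pi
from theascan.introgression import patterson_d, modified_fd
from theascan.simulate import SimConfig, preset, simulate_populations
from theascan.windows import make_windows

TINY = dict(
    n_e=50, mu=1e-6, seq_len=100_000, recomb_rate=5e-7,
    t_split_out=40, t_split_p3=30, t_split_p12=20, admix_time=1, burn_in=20,
    sample_sizes=(("P1", 8), ("P2", 8), ("P3", 8), ("O", 8)),
)


def _mean_pi_per_site(matrix, spec, pop):
    haps = matrix.pop_haplotypes(spec, pop)
    p, n = haplotype_freqs(haps)
    seg = (p > 0) & (p < 1)
    if not seg.any():
        return 0.0
    return float(np.nansum(site_pi(p[seg], n[seg]))) / matrix.seq_len


class TestBasics:
    def test_deterministic_for_fixed_seed(self):
        a, _, _ = simulate_populations(SimConfig(seed=9, **TINY))
        b, _, _ = simulate_populations(SimConfig(seed=9, **TINY))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_no_mutation_no_sites(self):
        cfg = SimConfig(seed=1, **{**TINY, "mu": 0.0})
        m, _, _ = simulate_populations(cfg)
        assert len(m.positions) == 0

    def test_positions_sorted_unique_in_range(self):
        m, _, _ = simulate_populations(SimConfig(seed=2, **TINY))
        assert np.all(np.diff(m.positions) > 0)
        assert m.positions[0] >= 0 and m.positions[-1] < m.seq_len

    def test_event_order_validated(self):
        with pytest.raises(ValueError):
            SimConfig(t_split_out=10, t_split_p3=20, t_split_p12=5, admix_time=1)
        with pytest.raises(ValueError):
            SimConfig(admix_frac=1.5)

    def test_popspec_sample_layout(self):
        m, spec, _ = simulate_populations(SimConfig(seed=3, **TINY))
        assert len(spec.samples) == 32
        assert m.haplotypes.shape[0] == 64
        assert spec.samples_for("P2") == [f"P2_{i}" for i in range(8)]


class TestEquilibriumDiversity:
    def test_mean_pi_matches_4Nmu(self):
        """Within-population diversity equals theta = 4*N*mu (3 SE band)."""
        cfg0 = dict(TINY)
        pis = [
            _mean_pi_per_site(*simulate_populations(SimConfig(seed=100 + s, **cfg0))[:2], "P1")
            for s in range(30)
        ]
        theta = 4 * cfg0["n_e"] * cfg0["mu"]
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - theta) < 3 * se + 1e-12

    def test_pi_matches_msprime_oracle(self):
        """Independent coalescent simulator agrees on mean diversity."""
        import msprime

        cfg0 = dict(TINY)
        theta = 4 * cfg0["n_e"] * cfg0["mu"]
        ms_pis = []
        for s in range(30):
            ts = msprime.sim_ancestry(
                samples=8, population_size=cfg0["n_e"], sequence_length=cfg0["seq_len"],
                recombination_rate=cfg0["recomb_rate"], random_seed=s + 1,
            )
            ts = msprime.sim_mutations(ts, rate=cfg0["mu"], random_seed=s + 1)
            ms_pis.append(ts.diversity() )
        wf_pis = [
            _mean_pi_per_site(*simulate_populations(SimConfig(seed=200 + s, **cfg0))[:2], "P1")
            for s in range(30)
        ]
        # both estimate theta; their means must be statistically indistinguishable
        t, p = stats.ttest_ind(ms_pis, wf_pis, equal_var=False)
        assert p > 0.01
        assert np.mean(wf_pis) == pytest.approx(theta, rel=0.35)

    def test_folded_sfs_neutral_shape(self):
        """Folded SFS follows the 1/b + 1/(n-b) neutral shape.

        Bin proportions are compared across replicate genomes with
        replicate-based standard errors: linked sites share genealogies,
        so within-genome bin counts are far from multinomial and a naive
        chi-square GOF would reject even a perfect simulator.
        """
        props = []
        n = None
        for s in range(10):
            m, spec, _ = simulate_populations(SimConfig(seed=400 + s, **TINY))
            haps = m.pop_haplotypes(spec, "P1")
            sfs = folded_sfs(haps)
            n = haps.shape[0]
            props.append(sfs / sfs.sum())
        props = np.array(props)
        expected = np.array([
            (1.0 / b + 1.0 / (n - b)) / (1 + (b == n - b)) for b in range(1, n // 2 + 1)
        ])
        expected = expected / expected.sum()
        mean = props.mean(axis=0)
        se = props.std(axis=0, ddof=1) / np.sqrt(len(props))
        t = (mean - expected) / np.maximum(se, 1e-12)
        assert np.all(np.abs(t) < 5.0)  # ~Bonferroni bound at alpha 0.01, df 9


class TestDemographicSignals:
    def test_complete_replacement_gives_positive_d(self):
        """admix_frac=1 just before sampling: P2 is drawn from the P3 pool."""
        cfg = SimConfig(seed=5, admix_frac=1.0, **TINY)
        m, spec, _ = simulate_populations(cfg)
        f = {p: haplotype_freqs(m.pop_haplotypes(spec, p))[0] for p in ("P1", "P2", "P3", "O")}
        res = patterson_d(f["P1"], f["P2"], f["P3"], f["O"])
        assert res.D > 0.3

    def test_mean_fd_increases_with_admixture_fraction(self):
        """Rank test: replicate mean f_d rises over pulse fractions 0..0.5."""
        fracs, rep_means = [], []
        for frac in (0.0, 0.05, 0.2, 0.5):
            for s in range(3):
                cfg = preset("pulse", seed=310 + s, admix_frac=frac)
                m, spec, _ = simulate_populations(cfg)
                f = {p: haplotype_freqs(m.pop_haplotypes(spec, p))[0]
                     for p in ("P1", "P2", "P3", "O")}
                wins = make_windows({m.chrom: m.seq_len}, 100_000, 100_000)
                fws = modified_fd(f["P1"], f["P2"], f["P3"], f["O"], m.positions, wins)
                ok = [w.fd for w in fws if not w.excluded and np.isfinite(w.fd)]
                fracs.append(frac)
                rep_means.append(np.mean(ok))
        rho, p = stats.spearmanr(fracs, rep_means)
        assert rho > 0
        assert p / 2 < 0.05  # one-sided

    def test_completed_sweep_fixes_selected_allele_and_block(self):
        cfg = preset("sweep", seed=11)
        m, spec, truth = simulate_populations(cfg)
        ha = m.pop_haplotypes(spec, "P1")
        i = int(np.flatnonzero(m.positions == truth.sel_pos)[0])
        assert ha[:, i].mean() == 1.0
        hb = m.pop_haplotypes(spec, "P2")
        assert hb[:, i].mean() < 0.5
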