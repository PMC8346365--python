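"""Synthetic-data evaluation runs: the package exercising itself end to end.

Each helper simulates one replicate under a named preset (the scaled
study conditions documented in docs/methods.md), runs the corresponding
scan, and reduces it to the quantity of interest: a genome-wide D
Z-score, a genome mean f_d, a sweep-detection outcome, ASE power/size,
or a recovered switch-error rate.  Both the test suite and
``scripts/acceptance.py`` are thin loops over these functions.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .ase import call_ase, classify_all_genes
from .diversity import haplotype_freqs, tail_indices, window_diversity
from .introgression import modified_fd, patterson_d
from .phasing import switch_error
from .selection import sweep_consensus, xpehh
from .simulate import (
    ExprSimConfig,
    PhasingSimConfig,
    preset,
    simulate_expression,
    simulate_phasing,
    simulate_populations,
)
from .windows import make_windows

D_BLOCK_SIZE = 40_000       # jackknife block for the 400-kb pulse/neutral genomes
FD_WINDOW = 100_000         # non-overlapping f_d windows
SWEEP_GAP = 20_000          # consensus cluster gap at the sweep preset's footprint scale


def _four_pop_freqs(matrix, spec):
    return {p: haplotype_freqs(matrix.pop_haplotypes(spec, p))[0]
            for p in ("P1", "P2", "P3", "O")}


def dstat_replicate(seed: int, admix_frac: float = 0.0) -> Tuple[float, float]:
    """Genome-wide Patterson's D and jackknife Z for one simulated genome."""
    name = "pulse" if admix_frac > 0 else "neutral"
    cfg = preset(name, seed=seed, admix_frac=admix_frac)
    matrix, spec, _ = simulate_populations(cfg)
    f = _four_pop_freqs(matrix, spec)
    res = patterson_d(f["P1"], f["P2"], f["P3"], f["O"],
                      positions=matrix.positions, block_size=D_BLOCK_SIZE)
    return res.D, res.Z


def fd_genome_mean(seed: int, admix_frac: float) -> float:
    """Mean modified f_d over non-excluded 100-kb windows of one pulse genome."""
    cfg = preset("pulse", seed=seed, admix_frac=admix_frac)
    matrix, spec, _ = simulate_populations(cfg)
    f = _four_pop_freqs(matrix, spec)
    windows = make_windows({matrix.chrom: matrix.seq_len}, FD_WINDOW, FD_WINDOW)
    fws = modified_fd(f["P1"], f["P2"], f["P3"], f["O"], matrix.positions, windows)
    vals = [w.fd for w in fws if not w.excluded and np.isfinite(w.fd)]
    return float(np.mean(vals))


def sweep_replicate(seed: int, sel_coeff: Optional[float] = None) -> Tuple[bool, float]:
    """One full sweep-consensus scan on the sweep preset.

    Returns (selected site covered by a retained region, fraction of the
    genome covered by retained regions).  With ``sel_coeff=0`` the run is
    the neutral false-positive control.
    """
    overrides = {} if sel_coeff is None else {"sel_coeff": sel_coeff}
    cfg = preset("sweep", seed=seed, **overrides)
    matrix, spec, truth = simulate_populations(cfg)
    ha = matrix.pop_haplotypes(spec, "P1")
    hb = matrix.pop_haplotypes(spec, "P2")
    scores = xpehh(ha, hb, matrix.positions)
    candidates = [s.position for s in scores if s.candidate]
    windows = make_windows({matrix.chrom: matrix.seq_len}, 10_000, 5_000)
    wd = window_diversity(ha, matrix.positions, windows,
                          [matrix.pop_genotypes(spec, "P1"), matrix.pop_genotypes(spec, "P2")])
    tajd_idx = tail_indices([d.tajd for d in wd], 0.05, "lower")
    fst_idx = tail_indices([d.fst for d in wd], 0.05, "upper")
    regions = sweep_consensus(
        matrix.chrom, candidates,
        [wd[i].window for i in tajd_idx], [wd[i].window for i in fst_idx],
        gap=SWEEP_GAP,
    )
    covered = truth.sel_pos is not None and any(
        r.start <= truth.sel_pos < r.end for r in regions
    )
    frac = sum(r.end - r.start for r in regions) / matrix.seq_len
    return covered, float(frac)


def ase_metrics(seed: int) -> Dict[str, float]:
    """Power / null-positive rate / class recovery of the ASE pipeline."""
    null_cfg = ExprSimConfig(n_genes=1000, n_tissues=2, n_reps=3, ase_frac=0.0,
                             noise_sd=0.3, seed=seed)
    expr, _ = simulate_expression(null_cfg)
    classes = classify_all_genes(call_ase(expr))
    null_rate = sum(1 for c in classes.values() if c != "none") / null_cfg.n_genes

    power_cfg = ExprSimConfig(n_genes=400, n_tissues=6, n_reps=3, ase_frac=0.3,
                              effect_log2fc=3.0, shifting_frac=0.25, noise_sd=0.3,
                              seed=seed + 1)
    expr, truth = simulate_expression(power_cfg)
    classes = classify_all_genes(call_ase(expr))
    planted = [g for g, lab in truth.items() if lab != "none"]
    power = sum(1 for g in planted if classes[g] != "none") / len(planted)
    recovery = sum(1 for g in planted if classes[g] == truth[g]) / len(planted)
    return {"power": power, "null_rate": null_rate, "class_recovery": recovery}


def switch_error_recovery(eps: float, seed: int, n_snps: int = 10_000) -> float:
    """Estimated switch-error rate of a phasing corrupted at rate ``eps``."""
    cfg = PhasingSimConfig(n_snps=n_snps, n_blocks=20, switch_rate=eps, seed=seed)
    sim = simulate_phasing(cfg)
    test = {(s.chrom, s.pos): s.phase for s in sim.test}
    return switch_error(sim.truth, test).rate
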