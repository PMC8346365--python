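"""Synthetic data with known ground truth for every pipeline stage.

Three generators live here:

* :func:`simulate_populations` — a forward-in-time Wright–Fisher model of
  four populations related as (((P1, P2), P3), O), with an optional single
  admixture pulse from P3 into P2 and an optional selective sweep.  The
  ancestral population is initialized at neutral mutation–drift
  equilibrium (site counts at derived-allele count i are Poisson with
  mean theta_L / i), then haplotypes evolve by binomial resampling with
  recombination under the infinite-sites approximation (each mutation
  hits a fresh integer position, so all sites stay biallelic).  The
  derived allele is coded 1 and is ancestral (0) in the outgroup's
  ancestor, so outgroup polarization is exact by construction.

* :func:`simulate_expression` — replicate-level allele FPKM tables with
  planted allele-specific-expression effects (consistent or
  direction-shifting between tissues) on a log-normal noise model.

* :func:`simulate_phasing` — a block-tagged truth phasing over
  heterozygous sites plus a corrupted copy with switch errors injected at
  a known per-site rate.

The sweep follows a deterministic logistic frequency trajectory
conditioned on fixation; haplotypes hitchhike through a single
non-recombining block around the selected site, while the rest of the
chromosome recombines at a fixed per-bp rate.  All outputs are
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phasing import PhasedSnp


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class SimConfig:
    """Demography and sampling for the four-population simulator.

    Times are in generations before present, oldest first; sizes are
    diploids.  ``mu`` defaults to the per-generation per-site rate used
    for tea demographic inference (6.5e-9) with a 3-year generation time;
    scans on synthetic data use scaled-up rates (see presets).
    """

    n_e: int = 100
    mu: float = 6.5e-9
    gen_time_years: float = 3.0
    seq_len: int = 500_000
    recomb_rate: float = 2.5e-7        # per bp per generation; no field default is claimed
    t_split_out: int = 300
    t_split_p3: int = 150
    t_split_p12: int = 60
    admix_time: int = 20
    admix_frac: float = 0.0
    sel_coeff: float = 0.0
    sel_pop: str = "P1"
    sel_pos: Optional[int] = None      # default: middle of the sequence
    sweep_block: int = 20_000          # half-width of the non-recombining hitchhiking block
    burn_in: int = 50
    sample_sizes: Tuple[Tuple[str, int], ...] = (("P1", 10), ("P2", 10), ("P3", 10), ("O", 10))
    seed: int = 0

    def __post_init__(self):
        if not (self.t_split_out > self.t_split_p3 > self.t_split_p12 > self.admix_time >= 0):
            raise ValueError(
                "event times must satisfy t_split_out > t_split_p3 > t_split_p12 > admix_time >= 0"
            )
        if not 0.0 <= self.admix_frac <= 1.0:
            raise ValueError("admix_frac must lie in [0, 1]")
        if self.n_e <= 0 or self.seq_len <= 0 or any(n <= 0 for _, n in self.sample_sizes):
            raise ValueError("all sizes must be positive")
        if self.sel_coeff < 0:
            raise ValueError("sel_coeff must be >= 0")
        if self.sel_coeff > 0 and self.sel_pop not in ("P1", "P2", "P3", "O"):
            raise ValueError(f"unknown selected population {self.sel_pop!r}")


@dataclass(frozen=True)
class ExprSimConfig:
    n_genes: int = 200
    n_tissues: int = 6
    n_reps: int = 3
    ase_frac: float = 0.2
    effect_log2fc: float = 3.0
    shifting_frac: float = 0.25
    noise_sd: float = 0.3              # replicate-level SD on the log2 scale
    seed: int = 0

    def __post_init__(self):
        for name in ("ase_frac", "shifting_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reps < 2:
            raise ValueError("need n_reps >= 2")


@dataclass(frozen=True)
class PhasingSimConfig:
    n_snps: int = 10_000
    n_blocks: int = 20
    switch_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.n_snps >= self.n_blocks >= 1:
            raise ValueError("need n_snps >= n_blocks >= 1")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# containers

@dataclass
class PopulationSpec:
    """Sample -> population map with P1/P2/P3/O (or wild/landrace/elite) roles."""

    samples: List[str]
    population: Dict[str, str]
    role: Dict[str, str]

    def samples_for(self, pop: str) -> List[str]:
        return [s for s in self.samples if self.population[s] == pop]


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes: rows 2i, 2i+1 belong to diploid ``samples[i]``."""

    chrom: str
    seq_len: int
    positions: np.ndarray          # 0-based, sorted
    haplotypes: np.ndarray         # (2 * n_samples, S) int8, -1 = missing
    samples: List[str]

    def sample_rows(self, spec: PopulationSpec, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if spec.population[s] == pop]
        rows = np.array([[2 * i, 2 * i + 1] for i in idx], dtype=np.int64).ravel()
        return rows

    def pop_haplotypes(self, spec: PopulationSpec, pop: str) -> np.ndarray:
        return self.haplotypes[self.sample_rows(spec, pop)]

    def pop_genotypes(self, spec: PopulationSpec, pop: str) -> np.ndarray:
        """Diploid dosage matrix (n x S) with -1 where either allele is missing."""
        h = self.pop_haplotypes(spec, pop)
        a, b = h[0::2], h[1::2]
        dos = a + b
        dos[(a < 0) | (b < 0)] = -1
        return dos


@dataclass
class SimTruth:
    admix_frac: float
    admix_time: int
    sel_pos: Optional[int]
    sel_pop: Optional[str]
    sel_coeff: float
    sweep_start: Optional[int] = None


# ---------------------------------------------------------------------------
# Wright-Fisher machinery

def _equilibrium_init(rng: np.random.Generator, two_n: int, theta_l: float, seq_len: int,
                      used: set) -> Tuple[np.ndarray, List[int]]:
    """Stationary neutral state: Poisson(theta_L / i) sites at derived count i."""
    cols: List[np.ndarray] = []
    poss: List[int] = []
    for i in range(1, two_n):
        k = rng.poisson(theta_l / i)
        for _ in range(k):
            pos = int(rng.integers(seq_len))
            while pos in used:
                pos = int(rng.integers(seq_len))
            used.add(pos)
            col = np.zeros(two_n, dtype=np.int8)
            col[rng.choice(two_n, size=i, replace=False)] = 1
            cols.append(col)
            poss.append(pos)
    if not cols:
        return np.zeros((two_n, 0), dtype=np.int8), []
    return np.column_stack(cols), poss


def _gamete(h1: np.ndarray, h2: np.ndarray, positions: np.ndarray, xs: np.ndarray,
            force_pos: Optional[int] = None) -> np.ndarray:
    """One recombinant gamete of two haplotypes with crossovers at ``xs``.

    ``force_pos``: guarantee the segment covering that position comes from h1.
    """
    if len(xs) == 1:
        from1 = positions <= xs[0]
        if force_pos is not None and not force_pos <= xs[0]:
            from1 = ~from1
    else:
        xs = np.sort(xs)
        seg = np.searchsorted(xs, positions, side="right")
        from1 = seg % 2 == 0
        if force_pos is not None and np.searchsorted(xs, force_pos, side="right") % 2 == 1:
            from1 = ~from1
    return np.where(from1, h1, h2).astype(np.int8)


def _next_generation(
    H: np.ndarray,
    out: np.ndarray,
    positions: np.ndarray,
    seq_len: int,
    r_bp: float,
    rng: np.random.Generator,
    donor: Optional[Tuple[np.ndarray, float]] = None,
    sweep: Optional[Tuple[int, int, Tuple[int, int]]] = None,
) -> None:
    """Binomial-resampling generation step (random union of gametes).

    Writes the offspring haplotypes into ``out``.  ``donor`` = (donor
    matrix, fraction): each gamete is drawn from the donor pool with that
    probability (the admixture pulse).  ``sweep`` = (selected column,
    target carrier count, (block_lo, block_hi)): carrier status at the
    selected site is forced to the deterministic trajectory and
    crossovers inside the block are suppressed.  Gametes with zero, one
    or two crossovers (almost all of them) are built in vectorized
    batches; rarer multi-crossover gametes fall back to a per-gamete path.
    """
    n_h = H.shape[0]
    pos_f = positions.astype(np.float32)  # exact for positions < 2**24

    if sweep is None:
        src = np.zeros(n_h, dtype=bool)
        if donor is not None:
            src = rng.random(n_h) < donor[1]
        ncx = rng.poisson(r_bp * seq_len, size=n_h)
        own0 = (ncx == 0) & ~src
        out[own0] = H[rng.integers(n_h, size=int(own0.sum()))]
        if donor is not None:
            dn0 = (ncx == 0) & src
            out[dn0] = donor[0][rng.integers(donor[0].shape[0], size=int(dn0.sum()))]
        for n_cx in (1, 2):
            batch = (ncx == n_cx) & ~src
            k = int(batch.sum())
            if not k:
                continue
            p1 = rng.integers(n_h, size=k)
            p2 = rng.integers(n_h, size=k)
            xs = rng.uniform(0, seq_len, size=(k, n_cx)).astype(np.float32)
            if n_cx == 1:
                mask = pos_f[None, :] <= xs
            else:
                lo = xs.min(axis=1)[:, None]
                hi = xs.max(axis=1)[:, None]
                mask = (pos_f[None, :] <= lo) | (pos_f[None, :] > hi)
            out[batch] = np.where(mask, H[p1], H[p2])
        rest = (ncx > 2) | ((ncx > 0) & src)
        for g in np.flatnonzero(rest):
            pool = donor[0] if (donor is not None and src[g]) else H
            h1 = pool[rng.integers(pool.shape[0])]
            h2 = pool[rng.integers(pool.shape[0])]
            out[g] = _gamete(h1, h2, positions, rng.uniform(0, seq_len, ncx[g]))
        return

    sel_col, target, (blo, bhi) = sweep
    sel_pos = int(positions[sel_col])
    carriers = np.flatnonzero(H[:, sel_col] == 1)
    noncarr = np.flatnonzero(H[:, sel_col] != 1)
    target = int(min(max(target, 0), n_h))
    if len(carriers) == 0:
        target = 0
    if len(noncarr) == 0:
        target = n_h
    want = np.arange(n_h) < target
    h1_idx = np.empty(n_h, dtype=np.int64)
    if target:
        h1_idx[:target] = carriers[rng.integers(len(carriers), size=target)]
    if target < n_h:
        h1_idx[target:] = noncarr[rng.integers(len(noncarr), size=n_h - target)]
    h2_idx = rng.integers(n_h, size=n_h)
    bw = bhi - blo
    ncx = rng.poisson(r_bp * max(seq_len - bw, 0), size=n_h)  # block never recombines
    z = ncx == 0
    out[z] = H[h1_idx[z]]
    for n_cx in (1, 2):
        batch = ncx == n_cx
        k = int(batch.sum())
        if not k:
            continue
        u = rng.uniform(0, seq_len - bw, size=(k, n_cx))
        xs = np.where(u >= blo, u + bw, u).astype(np.float32)  # crossovers mapped outside the block
        if n_cx == 1:
            base = pos_f[None, :] <= xs
            covered = (sel_pos <= xs[:, 0])
        else:
            lo = np.sort(xs, axis=1)[:, :1]
            hi = np.sort(xs, axis=1)[:, 1:]
            base = (pos_f[None, :] <= lo) | (pos_f[None, :] > hi)
            covered = (sel_pos <= lo[:, 0]) | (sel_pos > hi[:, 0])
        mask = base ^ ~covered[:, None]  # force the block segment to come from h1
        out[batch] = np.where(mask, H[h1_idx[batch]], H[h2_idx[batch]])
    for g in np.flatnonzero(ncx > 2):
        u = rng.uniform(0, seq_len - bw, size=ncx[g])
        xs = np.where(u >= blo, u + bw, u)
        out[g] = _gamete(H[h1_idx[g]], H[h2_idx[g]], positions, xs, force_pos=sel_pos)


def _logistic_freq(t: int, s: float, two_n: int) -> float:
    p0 = 1.0 / two_n
    return p0 * math.exp(s * t) / (1.0 + p0 * (math.exp(s * t) - 1.0))


class _SimState:
    """Active populations over a shared, capacity-buffered column space.

    Each population owns two buffers (current and spare) so a generation
    step writes offspring without allocating; mutation columns are
    appended into reserved capacity instead of concatenating.
    """

    SLACK = 4096

    def __init__(self, pops: Dict[str, np.ndarray], positions: np.ndarray, used: set):
        self.used = used
        self.ncols = len(positions)
        self.cap = self.ncols + self.SLACK
        self.positions = np.empty(self.cap, dtype=np.int64)
        self.positions[: self.ncols] = positions
        self.pops: Dict[str, np.ndarray] = {}
        self._spare: Dict[str, np.ndarray] = {}
        for name, H in pops.items():
            self.add_pop(name, H)

    def add_pop(self, name: str, H: np.ndarray) -> None:
        buf = np.empty((H.shape[0], self.cap), dtype=np.int8)
        buf[:, : self.ncols] = H[:, : self.ncols]
        self.pops[name] = buf
        self._spare[name] = np.empty_like(buf)

    def split_pop(self, name: str, child_a: str, child_b: str) -> None:
        buf = self.pops.pop(name)
        spare = self._spare.pop(name)
        self.pops[child_a], self._spare[child_a] = buf, spare
        self.add_pop(child_b, buf)

    def view(self, name: str) -> np.ndarray:
        return self.pops[name][:, : self.ncols]

    def pos_view(self) -> np.ndarray:
        return self.positions[: self.ncols]

    def step_into_spare(self, name: str) -> Tuple[np.ndarray, np.ndarray]:
        return self.view(name), self._spare[name][:, : self.ncols]

    def swap(self, name: str) -> None:
        self.pops[name], self._spare[name] = self._spare[name], self.pops[name]

    def _grow(self, extra: int) -> None:
        new_cap = max(self.cap + self.SLACK, self.ncols + extra + self.SLACK)
        pos = np.empty(new_cap, dtype=np.int64)
        pos[: self.ncols] = self.positions[: self.ncols]
        self.positions = pos
        for name in list(self.pops):
            rows = self.pops[name].shape[0]
            buf = np.empty((rows, new_cap), dtype=np.int8)
            buf[:, : self.ncols] = self.pops[name][:, : self.ncols]
            self.pops[name] = buf
            self._spare[name] = np.empty_like(buf)
        self.cap = new_cap

    def add_mutations(self, rng: np.random.Generator, mu: float, seq_len: int) -> None:
        counts = {name: int(rng.poisson(H.shape[0] * mu * seq_len))
                  for name, H in ((n, self.view(n)) for n in self.pops)}
        k = sum(counts.values())
        if k == 0:
            return
        if self.ncols + k > self.cap:
            self._grow(k)
        new_pos: List[int] = []
        while len(new_pos) < k:
            for pos in rng.integers(seq_len, size=k - len(new_pos)):
                pos = int(pos)
                if pos not in self.used:       # infinite sites: collisions re-drawn
                    self.used.add(pos)
                    new_pos.append(pos)
        self.positions[self.ncols: self.ncols + k] = new_pos
        offset = 0
        for name in self.pops:
            block = self.pops[name][:, self.ncols: self.ncols + k]
            block[:] = 0
            m = counts[name]
            if m:
                rows = rng.integers(block.shape[0], size=m)
                block[rows, np.arange(offset, offset + m)] = 1
            offset += m
        self.ncols += k

    def prune(self, keep_pos: Optional[int] = None) -> None:
        """Drop columns lost or fixed across every active population."""
        total = sum(self.view(n).sum(axis=0) for n in self.pops)
        rows = sum(self.pops[n].shape[0] for n in self.pops)
        keep = (total > 0) & (total < rows)
        if keep_pos is not None:
            keep |= self.pos_view() == keep_pos
        if keep.all():
            return
        idx = np.flatnonzero(keep)
        k = len(idx)
        for name in self.pops:
            self.pops[name][:, :k] = self.pops[name][:, idx]
        self.positions[:k] = self.positions[idx]
        self.ncols = k


def simulate_populations(cfg: SimConfig) -> Tuple[HaplotypeMatrix, PopulationSpec, SimTruth]:
    """Run the four-population Wright-Fisher model and sample the present.

    Returns phased haplotypes for the sampled diploids of P1, P2, P3 and O
    (derived allele = 1, ancestral relative to the outgroup lineage = 0),
    the sample->population map, and the ground-truth record (admixture
    fraction and time, selected site).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    two_n = 2 * cfg.n_e
    theta_l = 4.0 * cfg.n_e * cfg.mu * cfg.seq_len
    used: set = set()
    anc, poss = _equilibrium_init(rng, two_n, theta_l, cfg.seq_len, used)
    state = _SimState({"ANC": anc}, np.array(poss, dtype=np.int64), used)

    sel_pos = cfg.sel_pos if cfg.sel_pos is not None else cfg.seq_len // 2
    sweep_duration = 0
    sweep_start: Optional[int] = None
    if cfg.sel_coeff > 0:
        sweep_duration = math.ceil(2.0 * math.log(two_n - 1) / cfg.sel_coeff)
        sweep_start = min(cfg.t_split_p12 - 1, sweep_duration + 5)
    block = (max(0, sel_pos - cfg.sweep_block), min(cfg.seq_len, sel_pos + cfg.sweep_block))

    def step_all(gbp: int) -> None:
        """Advance every active population one generation (to gbp - 1)."""
        pos = state.pos_view()
        for name in list(state.pops):
            donor = None
            sweep = None
            if name == "P2" and cfg.admix_frac > 0 and gbp == max(cfg.admix_time, 1):
                donor = (state.view("P3"), cfg.admix_frac)
            if (
                cfg.sel_coeff > 0
                and name == cfg.sel_pop
                and sweep_start is not None
                and gbp <= sweep_start
            ):
                sel_col_arr = np.flatnonzero(pos == sel_pos)
                if len(sel_col_arr):
                    t = sweep_start - gbp + 1
                    target = int(round(two_n * _logistic_freq(t, cfg.sel_coeff, two_n)))
                    sweep = (int(sel_col_arr[0]), max(target, 1), block)
            H, out = state.step_into_spare(name)
            _next_generation(H, out, pos, cfg.seq_len, cfg.recomb_rate, rng,
                             donor=donor, sweep=sweep)
            state.swap(name)
        state.add_mutations(rng, cfg.mu, cfg.seq_len)

    for _ in range(cfg.burn_in):
        step_all(cfg.t_split_out + 1)
        state.prune()

    # populations nobody samples (and that feed no pulse) need not be evolved
    sample_req = dict(cfg.sample_sizes)
    needed = {p for p, n in sample_req.items() if n > 0}
    if cfg.admix_frac > 0:
        needed.add("P3")

    def drop_unneeded(*names: str) -> None:
        for name in names:
            if name not in needed:
                state.pops.pop(name, None)
                state._spare.pop(name, None)

    for gbp in range(cfg.t_split_out, 0, -1):
        if gbp == cfg.t_split_out:
            state.split_pop("ANC", "O", "P123")
            drop_unneeded("O")
        if gbp == cfg.t_split_p3:
            state.split_pop("P123", "P3", "P12")
            drop_unneeded("P3")
        if gbp == cfg.t_split_p12:
            state.split_pop("P12", "P1", "P2")
            drop_unneeded("P1", "P2")
        if cfg.sel_coeff > 0 and sweep_start is not None and gbp == sweep_start:
            # inject the beneficial allele on one haplotype of the target pop
            if len(np.flatnonzero(state.pos_view() == sel_pos)) == 0:
                state.used.add(sel_pos)
                if state.ncols + 1 > state.cap:
                    state._grow(1)
                state.positions[state.ncols] = sel_pos
                for name in state.pops:
                    state.pops[name][:, state.ncols] = 0
                state.ncols += 1
            sel_col = int(np.flatnonzero(state.pos_view() == sel_pos)[0])
            tgt = state.pops[cfg.sel_pop]
            tgt[:, sel_col] = 0
            tgt[rng.integers(tgt.shape[0]), sel_col] = 1
        step_all(gbp)
        if gbp % 20 == 0:
            state.prune(keep_pos=sel_pos if cfg.sel_coeff > 0 else None)

    # sample diploids per population at the present
    sample_sizes = dict(cfg.sample_sizes)
    order = [p for p in ("P1", "P2", "P3", "O") if p in sample_sizes]
    rows_list, samples, pop_of = [], [], {}
    for pop in order:
        k = sample_sizes[pop]
        if 2 * k > two_n:
            raise ValueError(f"cannot sample {k} diploids from {cfg.n_e}")
        chosen = rng.choice(two_n, size=2 * k, replace=False)
        rows_list.append(state.view(pop)[chosen])
        for i in range(k):
            name = f"{pop}_{i}"
            samples.append(name)
            pop_of[name] = pop
    haps = np.concatenate(rows_list, axis=0)

    # keep sites segregating in the pooled sample (plus the selected site)
    counts = haps.sum(axis=0)
    keep = (counts > 0) & (counts < haps.shape[0])
    if cfg.sel_coeff > 0:
        keep |= state.pos_view() == sel_pos
    haps = haps[:, keep]
    positions = state.pos_view()[keep]
    order_idx = np.argsort(positions, kind="stable")
    haps = np.ascontiguousarray(haps[:, order_idx])
    positions = positions[order_idx]

    spec = PopulationSpec(samples, pop_of, {s: pop_of[s] for s in samples})
    truth = SimTruth(
        admix_frac=cfg.admix_frac,
        admix_time=cfg.admix_time,
        sel_pos=sel_pos if cfg.sel_coeff > 0 else None,
        sel_pop=cfg.sel_pop if cfg.sel_coeff > 0 else None,
        sel_coeff=cfg.sel_coeff,
        sweep_start=sweep_start,
    )
    matrix = HaplotypeMatrix("chr1", cfg.seq_len, positions, haps, samples)
    return matrix, spec, truth


# ---------------------------------------------------------------------------
# expression simulator

def simulate_expression(cfg: ExprSimConfig) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Replicate FPKM table with planted ASE effects and per-gene truth labels.

    Null genes share one log-normal mean between alleles; planted genes
    carry the configured |log2FC| between allele means, either in a fixed
    direction in every tissue (``consistent``) or switching direction
    between tissues (``shifting``).
    """
    rng = np.random.default_rng(cfg.seed)
    tissues = [f"T{t+1}" for t in range(cfg.n_tissues)]
    rows = []
    truth: Dict[str, str] = {}
    n_ase = int(round(cfg.ase_frac * cfg.n_genes))
    n_shift = int(round(cfg.shifting_frac * n_ase))
    for g in range(cfg.n_genes):
        gene = f"G{g+1:05d}"
        if g < n_ase - n_shift:
            label = "consistent"
        elif g < n_ase:
            label = "shifting" if cfg.n_tissues >= 2 else "consistent"
        else:
            label = "none"
        truth[gene] = label
        base = rng.normal(4.0, 1.5)
        if label == "consistent":
            dirs = np.full(cfg.n_tissues, 1 if rng.random() < 0.5 else -1)
        elif label == "shifting":
            dirs = np.where(rng.random(cfg.n_tissues) < 0.5, 1, -1)
            if np.all(dirs == dirs[0]):       # force both directions to appear
                dirs[rng.integers(cfg.n_tissues)] *= -1
        else:
            dirs = np.zeros(cfg.n_tissues)
        for t, tissue in enumerate(tissues):
            mu_t = base + rng.normal(0.0, 0.5)
            for allele, sign in (("A", +0.5), ("B", -0.5)):
                mean_log2 = mu_t + sign * dirs[t] * cfg.effect_log2fc
                for rep in range(cfg.n_reps):
                    fpkm = float(2.0 ** (mean_log2 + rng.normal(0.0, cfg.noise_sd)))
                    rows.append((gene, allele, tissue, rep + 1, fpkm))
    expr = pd.DataFrame(rows, columns=["gene", "allele", "tissue", "replicate", "fpkm"])
    return expr, truth


# ---------------------------------------------------------------------------
# phasing simulator

@dataclass
class PhasingSim:
    truth: List[PhasedSnp]
    test: List[PhasedSnp]
    flipped: np.ndarray     # boolean per truth SNP


def simulate_phasing(
    cfg: PhasingSimConfig,
    hap_a: Optional[np.ndarray] = None,
    hap_b: Optional[np.ndarray] = None,
    positions: Optional[np.ndarray] = None,
    chrom: str = "chr1",
) -> PhasingSim:
    """Truth phasing over heterozygous sites plus a switch-corrupted copy.

    When a chromosome's two haplotypes are supplied, the truth phase of
    each heterozygous site records which haplotype carries the alternate
    allele; otherwise random phases over ``n_snps`` synthetic sites are
    used.  Sites are partitioned into ``n_blocks`` contiguous blocks and
    each site's test phase is flipped independently with probability
    ``switch_rate`` (so the number of flips is Binomial(n_snps, rate)).
    """
    rng = np.random.default_rng(cfg.seed)
    if hap_a is not None:
        hap_a = np.asarray(hap_a)
        hap_b = np.asarray(hap_b)
        het = np.flatnonzero(hap_a != hap_b)
        if len(het) == 0:
            raise ValueError("no heterozygous sites")
        het = het[: cfg.n_snps]
        pos = (np.asarray(positions)[het] if positions is not None else het).astype(np.int64)
        phase = (hap_a[het] == 1).astype(int)     # 1: haplotype A carries the alternate
        n = len(het)
    else:
        n = cfg.n_snps
        pos = np.arange(n, dtype=np.int64) * 100 + 100
        phase = rng.integers(0, 2, size=n)
    bounds = np.linspace(0, n, cfg.n_blocks + 1).astype(int)
    block_of = np.zeros(n, dtype=int)
    for b in range(cfg.n_blocks):
        block_of[bounds[b]: bounds[b + 1]] = b
    flipped = rng.random(n) < cfg.switch_rate
    truth = [PhasedSnp(chrom, int(pos[i]), int(block_of[i]), int(phase[i])) for i in range(n)]
    test = [
        PhasedSnp(chrom, int(pos[i]), int(block_of[i]), int(phase[i]) ^ int(flipped[i]))
        for i in range(n)
    ]
    return PhasingSim(truth, test, flipped)


# ---------------------------------------------------------------------------
# presets: the scaled study conditions used by scans on synthetic data

PRESETS: Dict[str, SimConfig] = {
    # neutral four-population history, no gene flow, no sweep
    "neutral": SimConfig(
        n_e=100, mu=2.0e-6, seq_len=400_000, recomb_rate=5.0e-7,
        t_split_out=320, t_split_p3=250, t_split_p12=40, admix_time=1,
        burn_in=0,
    ),
    # single pulse P3 -> P2 of fraction 0.2 one generation before sampling
    "pulse": SimConfig(
        n_e=100, mu=2.0e-6, seq_len=400_000, recomb_rate=5.0e-7,
        t_split_out=320, t_split_p3=250, t_split_p12=40, admix_time=1,
        admix_frac=0.2, burn_in=0,
    ),
    # completed hard sweep in P1 against a recently diverged sister population
    # (larger N keeps neutral haplotype sharing short relative to the footprint)
    "sweep": SimConfig(
        n_e=1000, mu=2.5e-7, seq_len=300_000, recomb_rate=1.6e-6,
        t_split_out=64, t_split_p3=62, t_split_p12=60, admix_time=1,
        sel_coeff=0.5, sel_pop="P1", sweep_block=15_000, burn_in=50,
        sample_sizes=(("P1", 10), ("P2", 10)),
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """A named preset config, optionally with field overrides (e.g. seed)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)
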