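"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 (via pysam; POS is kept 1-based on disk and converted to 0-based
internally), BED3 (0-based half-open), the popmap TSV
``sample<TAB>population<TAB>role``, GFF3 gene models (via gffutils), and
the allele-level expression TSV ``gene, allele, tissue, replicate, fpkm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .alleles import GeneModel
from .intervals import IntervalSet
from .simulate import HaplotypeMatrix, PopulationSpec


@dataclass
class VariantRecord:
    """One VCF record with per-sample genotypes (allele-index pairs)."""

    chrom: str
    pos: int                       # 1-based, as in the VCF
    ref: str
    alts: Tuple[str, ...]
    total_depth: Optional[int]
    genotypes: List[Tuple[Optional[int], Optional[int]]]
    phased: bool = False
    phase_block: Optional[int] = None

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def missing_rate(self) -> float:
        """Fraction of samples with any missing allele call."""
        if not self.genotypes:
            return 0.0
        miss = sum(1 for a, b in self.genotypes if a is None or b is None)
        return miss / len(self.genotypes)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str) -> Tuple[List[str], Iterator[VariantRecord]]:
    """Open a VCF and return (sample names, record iterator)."""
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)

    def _iter() -> Iterator[VariantRecord]:
        for i, rec in enumerate(vf):
            try:
                yield _convert_record(rec, samples)
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"{path}: malformed record #{i + 1} at {rec.chrom}:{rec.pos}: {exc}") from exc
        vf.close()

    return samples, _iter()


def _convert_record(rec, samples: Sequence[str]) -> VariantRecord:
    gts: List[Tuple[Optional[int], Optional[int]]] = []
    phased = True
    phase_block = None
    total_dp = rec.info.get("DP")
    dp_sum = 0
    dp_seen = False
    for s in samples:
        sd = rec.samples[s]
        gt = sd.get("GT") or (None, None)
        if len(gt) == 1:
            gt = (gt[0], gt[0])
        gts.append((gt[0], gt[1]))
        phased = phased and bool(sd.phased)
        ps = sd.get("PS")
        if ps is not None and phase_block is None:
            phase_block = int(ps)
        dp = sd.get("DP")
        if dp is not None:
            dp_sum += int(dp)
            dp_seen = True
    if total_dp is None and dp_seen:
        total_dp = dp_sum
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alts=tuple(rec.alts or ()),
        total_depth=int(total_dp) if total_dp is not None else None,
        genotypes=gts,
        phased=phased and len(samples) > 0,
        phase_block=phase_block,
    )


def _vcf_header(samples: Sequence[str], contigs: Dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf_matrix(
    matrix: HaplotypeMatrix,
    path: str,
    depth: int = 30,
    phase_block: int = 1,
) -> None:
    """Write phased haplotypes as a VCF (REF=A ancestral, ALT=T derived).

    Every genotype is phased ("|") and tagged with a single phase block;
    a constant per-site INFO DP of ``depth`` per haplotype is recorded so
    depth filters behave sensibly on synthetic data.
    """
    header = _vcf_header(matrix.samples, {matrix.chrom: matrix.seq_len})
    with pysam.VariantFile(path, "w", header=header) as vf:
        H = matrix.haplotypes
        for j, pos in enumerate(matrix.positions):
            rec = vf.new_record(
                contig=matrix.chrom, start=int(pos), alleles=("A", "T"), qual=60
            )
            rec.info["DP"] = depth * len(matrix.samples)
            for i, s in enumerate(matrix.samples):
                a, b = int(H[2 * i, j]), int(H[2 * i + 1, j])
                rec.samples[s]["GT"] = (a if a >= 0 else None, b if b >= 0 else None)
                rec.samples[s].phased = True
                rec.samples[s]["PS"] = phase_block
            vf.write(rec)


def write_vcf_records(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    contigs: Dict[str, int],
    path: str,
) -> None:
    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(
                contig=r.chrom, start=r.pos0, alleles=(r.ref,) + tuple(r.alts), qual=60
            )
            if r.total_depth is not None:
                rec.info["DP"] = r.total_depth
            for s, gt in zip(samples, r.genotypes):
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = r.phased
                if r.phase_block is not None:
                    rec.samples[s]["PS"] = r.phase_block
            vf.write(rec)


def matrix_from_vcf(path: str, popmap: Optional[PopulationSpec] = None) -> Tuple[HaplotypeMatrix, List[str]]:
    """Load a phased biallelic VCF into a haplotype matrix.

    Returns the matrix and a list of warnings (skipped records).  Sites
    that are not biallelic SNPs are skipped.
    """
    vf = pysam.VariantFile(path)
    contig_lengths = {name: c.length for name, c in vf.header.contigs.items()}
    vf.close()
    samples, records = read_vcf(path)
    positions: List[int] = []
    cols: List[np.ndarray] = []
    skipped: List[str] = []
    chrom = None
    maxpos = 0
    for r in records:
        if not (r.is_snp and r.is_biallelic):
            skipped.append(f"{r.chrom}:{r.pos} not a biallelic SNP")
            continue
        if chrom is None:
            chrom = r.chrom
        elif r.chrom != chrom:
            raise ValueError("matrix_from_vcf expects a single chromosome per file")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a, b) in enumerate(r.genotypes):
            col[2 * i] = -1 if a is None else a
            col[2 * i + 1] = -1 if b is None else b
        positions.append(r.pos0)
        cols.append(col)
        maxpos = max(maxpos, r.pos)
    haps = np.column_stack(cols) if cols else np.zeros((2 * len(samples), 0), dtype=np.int8)
    seq_len = contig_lengths.get(chrom) or maxpos + 1
    matrix = HaplotypeMatrix(chrom or "chr1", int(seq_len), np.array(positions, dtype=np.int64), haps, list(samples))
    return matrix, skipped


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str) -> IntervalSet:
    """Read BED3 (0-based half-open) into an IntervalSet."""
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            per_chrom.setdefault(parts[0], []).append((start, end))
    return IntervalSet(per_chrom)


def write_bed(ivs: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in ivs:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# popmap

def read_popmap(path: str) -> PopulationSpec:
    """Read ``sample<TAB>population[<TAB>role]`` into a PopulationSpec."""
    samples: List[str] = []
    pop: Dict[str, str] = {}
    role: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected sample<TAB>population[<TAB>role]")
            s = parts[0]
            samples.append(s)
            pop[s] = parts[1]
            role[s] = parts[2] if len(parts) > 2 else parts[1]
    return PopulationSpec(samples, pop, role)


def write_popmap(spec: PopulationSpec, path: str) -> None:
    with open(path, "w") as fh:
        for s in spec.samples:
            fh.write(f"{s}\t{spec.population[s]}\t{spec.role.get(s, spec.population[s])}\n")


def match_samples(spec: PopulationSpec, vcf_samples: Sequence[str]) -> PopulationSpec:
    """Restrict a popmap to the samples actually present in a VCF.

    Popmap entries absent from the VCF are reported and skipped with a
    warning (and vice versa VCF samples without a popmap entry).
    """
    present = [s for s in spec.samples if s in set(vcf_samples)]
    missing = [s for s in spec.samples if s not in set(vcf_samples)]
    unmapped = [s for s in vcf_samples if s not in spec.population]
    if missing:
        warnings.warn(f"popmap samples absent from VCF, skipped: {missing}")
    if unmapped:
        warnings.warn(f"VCF samples without popmap entry, ignored: {unmapped}")
    return PopulationSpec(
        present,
        {s: spec.population[s] for s in present},
        {s: spec.role.get(s, spec.population[s]) for s in present},
    )


# ---------------------------------------------------------------------------
# gene models & expression

def read_gene_models(path: str) -> List[GeneModel]:
    """Read GFF3 gene models as CDS interval lists (0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: Dict[str, GeneModel] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.attributes.get("ID", ["?"])[0]])
        gid = parents[0]
        gm = genes.get(gid)
        if gm is None:
            gm = GeneModel(gid, cds.seqid, cds.strand, [])
            genes[gid] = gm
        gm.cds.append((cds.start - 1, cds.end))  # GFF is 1-based inclusive
    for gm in genes.values():
        gm.cds.sort()
    return [genes[g] for g in sorted(genes)]


def read_expression(path: str) -> pd.DataFrame:
    """Read the allele-level expression TSV (gene, allele, tissue, replicate, fpkm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "allele", "tissue", "replicate", "fpkm"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    return df


def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
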