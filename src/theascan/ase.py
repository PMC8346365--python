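"""Allele-specific expression (ASE) calling and gene-level classification.

A gene x tissue test compares replicate FPKM values of the two alleles:
log2 fold change on pseudocounted means, a Welch t-test on log2(FPKM+1)
across replicates (or a pooled binomial test behind a flag), and BH FDR
across all gene x tissue tests.  A call is significant when
|log2FC| > 2 AND p < 0.05 AND q < 0.05.

Gene classes: ``consistent`` (significant in every tested tissue, always
toward the same allele), ``shifting`` (significant calls toward both
alleles), ``none`` otherwise.  A relaxed consistent mode (significant in
>= k tissues, never opposite) is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.1  # on FPKM means, avoids division by zero


@dataclass
class AseResult:
    gene: str
    tissue: str
    mean_fpkm_a: float
    mean_fpkm_b: float
    log2fc: float
    p: float
    q: float = math.nan
    direction: str = "none"   # 'A', 'B' or 'none'
    significant: bool = False


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(la, lb, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if not np.isfinite(p) else p


def _binomial_p(a: np.ndarray, b: np.ndarray) -> float:
    # pooled counts, rounded; tests departure from a 50:50 allelic ratio
    ka, kb = int(round(a.sum())), int(round(b.sum()))
    if ka + kb == 0:
        return 1.0
    return float(stats.binomtest(ka, ka + kb, 0.5).pvalue)


def call_ase(
    expr: pd.DataFrame,
    log2fc_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "ttest",
) -> List[AseResult]:
    """Per gene x tissue ASE tests with batch-wide BH correction.

    ``expr`` needs columns gene, allele ('A'/'B'), tissue, replicate, fpkm.
    Tissues with < 2 replicates for either allele are skipped with a
    warning.  ``test`` is 'ttest' (Welch on log2(FPKM+1) replicates) or
    'binomial' (pooled counts).
    """
    if test not in ("ttest", "binomial"):
        raise ValueError("test must be 'ttest' or 'binomial'")
    results: List[AseResult] = []
    for (gene, tissue), sub in expr.groupby(["gene", "tissue"], sort=True):
        a = sub.loc[sub["allele"] == "A", "fpkm"].to_numpy(dtype=float)
        b = sub.loc[sub["allele"] == "B", "fpkm"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"{gene}/{tissue}: <2 replicates per allele, skipped")
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        log2fc = math.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
        p = _welch_p(a, b) if test == "ttest" else _binomial_p(a, b)
        results.append(AseResult(gene, tissue, mean_a, mean_b, log2fc, p))

    if results:
        _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q = float(qv)
            r.significant = (
                abs(r.log2fc) > log2fc_threshold and r.p < alpha and r.q < alpha
            )
            if r.significant:
                r.direction = "A" if r.log2fc > 0 else "B"
    return results


def classify_gene(
    gene_results: Sequence[AseResult],
    mode: str = "strict",
    min_tissues: int = 1,
) -> str:
    """Gene-level ASE class from its per-tissue calls.

    strict: ``consistent`` requires significance in ALL tested tissues with
    one direction; relaxed: significant in >= ``min_tissues`` tissues and
    never toward the opposite allele.  ``shifting`` whenever significant
    calls toward both alleles exist.  Otherwise ``none``.
    """
    dirs = [r.direction for r in gene_results if r.significant]
    if not dirs:
        return "none"
    if "A" in dirs and "B" in dirs:
        return "shifting"
    if mode == "strict":
        return "consistent" if len(dirs) == len(gene_results) else "none"
    if mode == "relaxed":
        return "consistent" if len(dirs) >= min_tissues else "none"
    raise ValueError("mode must be 'strict' or 'relaxed'")


def classify_all_genes(results: Sequence[AseResult], mode: str = "strict", min_tissues: int = 1) -> Dict[str, str]:
    by_gene: Dict[str, List[AseResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    return {g: classify_gene(rs, mode=mode, min_tissues=min_tissues) for g, rs in by_gene.items()}
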