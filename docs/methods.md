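# Methods

`theascan` re-implements, as a tested library, the statistical battery used
in haplotype-resolved crop-genome studies: phasing switch-error evaluation,
allele pairing and allele-specific expression (ASE) classification,
SNP quality filtering, windowed diversity statistics, frequency-based
introgression statistics, and a cross-population selective-sweep consensus
scan. A forward-in-time Wright–Fisher simulator generates every input the
pipeline consumes with known ground truth, so all downstream stages are
testable without any external data.

## Statistics

**Diversity.** Per-site nucleotide diversity is the unbiased mean pairwise
difference `2p(1−p)·n/(n−1)`; Watterson's estimator is `S/a1`; Tajima's D
uses the 1989 constants, with windows at `S = 0` flagged undefined and
excluded from percentile ranking (never set to 0, which would pile
artificial mass at the centre of the lowest-5% tail). Windowed π is
reported both as the window sum and per bp (sum divided by window length,
the VCFtools convention — not by genotyped sites; with sparse data the two
differ, and the per-bp convention is a documented choice, not a claim to
match any particular published denominator). F_ST is the Weir–Cockerham
(1984) diploid variance-component estimator with ratio-of-sums windowing;
Hudson's haplotype-level estimator is available as a cross-check. Default
windows are 10 kb with a 5-kb step.

**Introgression.** Patterson's D uses derived-allele frequencies in the
four-taxon arrangement (((P1,P2),P3),O): per site
`ABBA = (1−p1)p2p3(1−p4)`, `BABA = p1(1−p2)p3(1−p4)`,
`D = (ΣABBA−ΣBABA)/(ΣABBA+ΣBABA)`, with a weighted delete-one block
jackknife (Busing et al. 1999) over contiguous blocks for the Z score.
The block size is exposed (default 5 Mb for real-scale data; the synthetic
evaluations use 40 kb, roughly ten blocks per simulated genome). The
windowed modified f_d (Martin et al. 2015) substitutes the higher of p2
and p3 as donor frequency in the denominator; windows with negative D and
f_d > 1 are excluded, and outliers are the top 5% of the non-excluded
distribution. f3(C; A, B) is the mean of `(c−a)(c−b)` with the
within-target sampling-bias correction `c(1−c)/(n_C−1)`; Z scores are
BH-adjusted by the monotone round trip p = Φ(z) → BH → Φ⁻¹(p_adj), with
raw Z always reported alongside (whether published "adjusted Z" values
used exactly this construction is unknowable; the round trip preserves
ranking). All estimators operate on called genotype frequencies, not
genotype likelihoods — a documented deviation from likelihood-based
pipelines with the same formulas.

**Percentile tails.** All "top/lowest 5%" rules flag the k most extreme
defined values with `k = ceil(0.05·m)`, ties inclusive. On 100 distinct
values this flags exactly 5; with ties all equally extreme values are
flagged; undefined (NaN) entries never are.

**Selection.** EHH partitions carrier haplotypes by identity of the
stretch from the core to the query site; iHH is its trapezoidal integral
over physical distance. XP-EHH pools both core alleles and integrates both
populations over a *common* span, truncated where the combined
two-population EHH falls below 0.05 (the selscan convention; per-population
truncation was tried and measured to be dominated by local diversity
fluctuations rather than selection). Scores `ln(iHH_A/iHH_B)` are
standardized genome-wide, unbinned; candidates are the top 5% of positive
standardized scores. Candidate sites are clustered into regions — each
site tags a gap/2 neighbourhood and regions are unions of neighbourhoods
(default gap 10 kb; the synthetic sweep evaluation uses 20 kb because the
simulated footprint is ~40 kb wide and sub-footprint gaps fragment one
sweep into flanking regions). A region is retained iff it overlaps a
lowest-5% Tajima's-D window of the putatively selected population or a
top-5% F_ST window of the contrast — which population's Tajima tail
validates is an explicit required argument, not a guess.

**Alleles and ASE.** Alleles are paired by >50% reciprocal coordinate
overlap (of the shorter gene) on the monoploid reference, greedily by
greatest overlap; byte-identical CDS pairs are collapsed to one allele.
Identity is unsubstituted bases over global-alignment length (gap columns
count toward the length); edit distance is Levenshtein. Ka/Ks is
Nei–Gojobori (1986) pathway counting with Jukes–Cantor correction;
changes to or from stop codons count as nonsynonymous and pathways through
stops are not discarded; proportions ≥ 0.75 flag saturation. The effect
classifier does a strand-aware codon lookup (premature stop, stop loss,
start loss, synonymous/nonsynonymous), calls splice_site for SNPs in the
2 bp at either intron end, and classifies CDS indels by length mod 3.
ASE per gene × tissue: log2 fold change of pseudocounted (ε = 0.1) mean
FPKM, a Welch t-test on log2(FPKM+1) across replicates (a pooled binomial
test is available behind a flag), BH FDR across all gene × tissue tests;
significant iff |log2FC| > 2 AND p < 0.05 AND q < 0.05 ("log fold change
greater than 2" is read as |log2FC| > 2, i.e. four-fold — log2 is the
field convention and the alternative reading would be far laxer). A gene
is `consistent` when significant toward the same allele in every tested
tissue (a relaxed ≥k-tissues mode exists), `shifting` when significant
calls go both ways.

**Phasing evaluation.** The truth set intersects two independent
block-phased call sets: within each maximal group sharing a block in both
inputs, the orientation maximizing agreement is absorbed and disagreeing
SNPs dropped. A test phasing is scored per truth block by minority count
after the mismatch-minimizing orientation, so a globally flipped phasing
scores zero; exact half/half blocks count n/2 and are flagged. Rates are
printed to one decimal with half-up rounding staged at two decimals then
one (the convention that reproduces conventional re-rounding of
percentages reported first at two decimals).

## The simulator

Forward-in-time Wright–Fisher, dependency-free, with four populations
related as (((P1,P2),P3),O), one optional admixture pulse P3→P2 and one
optional selective sweep. Haplotypes are 0/1 arrays over integer positions
under the infinite-sites approximation (collisions re-drawn), so every
site stays biallelic. The ancestral population is initialized at the
neutral stationary state — the number of sites at derived count *i* is
Poisson with mean θ_L/i — which is exact for the expectation and lets the
burn-in be short (it only has to build linkage structure, not diversity).
Reproduction is random union of gametes with Poisson crossovers;
generations with zero, one or two crossovers (the vast majority) are built
in vectorized batches. Per-site offspring counts were verified to be
exactly binomial, and mean per-site diversity matches θ = 4Nμ to under
1%, cross-checked against msprime as an independent coalescent oracle.

The sweep follows a deterministic logistic frequency trajectory
conditioned on fixation: the target carrier count at each generation is
set from `p(t) = p0·e^{st}/(1+p0(e^{st}−1))`, carrier gametes inherit a
single non-recombining hitchhiking block around the selected site, and
the rest of the chromosome recombines normally. The sweep starts
`duration + 5` generations before sampling (duration = `2·ln(2N−1)/s`),
clipped to after the P1/P2 split, so it is complete at sampling.

Defaults carry the study's stated provenance where it exists: mutation
rate 6.5e-9 per site per generation and a 3-year generation time. No
recombination rate is claimed by the source; it is a config field with a
scaled default. The scan evaluations use scaled-up rates so that
desk-scale genomes carry realistic site densities:

* **neutral / pulse** (D, f_d, diversity): N = 100 diploids, 400 kb,
  μ = 2e-6, r = 5e-7 (θ per site 8e-4), splits 320/250/40 generations ago,
  pulse one generation before sampling. The late pulse is deliberate:
  post-pulse drift at N = 100 otherwise moves the realized admixture
  fraction by ±0.1 per replicate, which is a property of tiny scaled
  populations rather than of the estimators being tested.
* **sweep**: N = 1000 diploids, 300 kb, μ = 2.5e-7, r = 1.6e-6, P1/P2
  split 60 generations ago (baseline F_ST ≈ 0.03, matching the weakly
  diverged landrace/elite contrasts this scan mimics), s = 0.5, block
  ±15 kb. The larger N is essential: in a 20-haplotype sample from
  N = 100, the closest pairs are near-pedigree relatives whose identical
  haplotypes span hundreds of kb and mimic sweeps; the neutral pooled-EHH
  identity scale is ≈ 5/(rN) bp and must sit well below the sweep
  footprint.

What the simulator does **not** emulate: realistic tea demography,
multiple pulses, background selection, mutation-rate or recombination
heterogeneity, genotyping error and missingness (fields accept missing
codes; the generator emits complete data). Passing parameter-recovery
tests therefore shows the estimators are correctly implemented and
well-calibrated under clean, scaled conditions — not that they are robust
to real-data artefacts.

## Evaluation sizes and known limitations

The synthetic evaluations use 50 replicates for the D-statistic
calibration/power and sweep-recovery checks, 8 per admixture level for
f_d recovery, 20 for the neutral scan control, and 10,000-SNP phasings
for switch-error recovery; `scripts/acceptance.py` reports the same
quantities at moderately smaller replicate counts (flags allow larger
runs).

One empirical control fails by construction at this simulation scale and
is reported honestly rather than tuned away: the neutral false-positive
control for the sweep consensus (retained regions covering < 1% of a
neutral genome). The top-5% candidate rule is *relative*, so ~2.5% of
sites are flagged under any neutral data; a single retained region spans
at least one cluster gap, which already exceeds 1% of a sub-megabase
genome; and the validating Tajima's-D / F_ST 5% tails are sliding windows
covering ~15% of the genome whose extremes are intrinsically correlated
with XP-EHH peaks (all three statistics respond to the same local
haplotype structure). On a gigabase genome whose LD scale is a few kb the
same battery retains a vanishing fraction; on 300 kb the floor is a few
percent. Measured neutral coverage at the sweep preset is reported by the
acceptance script.

Numerical conventions: tolerances of 1e-9 against brute-force oracles;
NaN marks every undefined statistic (S = 0 windows, zero-denominator f_d,
Ka/Ks at Ks = 0, saturated NG86 distances) and is excluded from ranking;
deterministic tie-breaks everywhere (first traceback in alignments,
lexicographic order in greedy pairing, ties-inclusive percentile flags);
all randomness flows from a single integer seed per run.
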