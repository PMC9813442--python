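# Methods

## Background and scope

In *Arabidopsis* seeds, the DEMETER (DME) glycosylase demethylates the
central cell genome before fertilization; the endosperm therefore inherits a
maternally demethylated genome (2 maternal : 1 paternal dosage in the
triploid tissue), while the embryo does not. Comparing embryo and endosperm
methylomes is the standard proxy for DME activity, and the loci it exposes
("DME targets") concentrate in small gene-flanking euchromatic transposons
and in heterochromatin. Linker histone H1 compacts heterochromatin;
removing it from the maternal genome is expected to widen DME's access to
heterochromatic targets. This package implements the full analysis stack
for that comparison — window-based CG DMR calling, methylome profiling,
chromatin-state composition, and SNP-based imprinting analytics — plus a
simulator that generates data with exactly this structure and the ground
truth to score recovery.

## DMR calling procedure

1. **Windows.** Per-cytosine counts (Bismark-style CX reports) are pooled
   into non-overlapping 50-bp windows anchored at coordinate 0 per
   chromosome; a 1-based position p belongs to window floor((p−1)/50). The
   two cytosines of a symmetric CG dyad are not merged — both contribute to
   the window pool, which is all the downstream statistics need. Windows
   with zero coverage are omitted.
2. **Window tests.** For co-covered windows where both samples have at
   least 10 sequenced cytosine calls (the informativeness floor — counting
   calls, not distinct covered positions, so that moderately CG-dense
   regions remain testable at ~20× coverage), the fractional difference
   Δ = frac_A − frac_B is computed, and windows with |Δ| ≥ 0.3 receive a
   two-sided Fisher's exact test on (m_A, u_A / m_B, u_B). Candidates
   require |Δ| ≥ 0.3 (inclusive) and p < 10⁻³.
3. **Merging.** Same-chromosome, same-direction candidates merge when the
   gap end(prev) → start(next) is ≤ 300 bp (inclusive). Opposite-direction
   candidates never merge: a region mixing hyper- and hypomethylated
   windows is not a coherent DMR and would dilute the pooled test.
4. **Region filter.** Each merged group is re-tested on its pooled raw
   counts (count-weighted, not averaged window fractions) and retained iff
   pooled |Δ| > 0.3 (strict), pooled p < 10⁻⁶, and span ≥ 100 bp. The
   asymmetry between the inclusive candidate threshold and the strict
   merged threshold is deliberate and kept literal. The 100-bp span rule
   implies ≥ 2 windows; no additional window-count floor is imposed.

No multiple-testing correction is applied anywhere — the procedure is
defined by fixed p-value cutoffs.

**Fisher's exact test.** Two-sided by the minimum-likelihood rule: the
p-value sums hypergeometric point probabilities (over tables with the
observed margins) no larger than the observed table's. For grand totals
≤ 500 the computation is exact integer arithmetic (binomial-coefficient
weights, integer comparison, one final division), so results are correct to
float precision and tie cases are decided exactly; larger tables delegate
to `scipy.stats.fisher_exact`, which implements the same rule in floats.
P-values are clamped to the smallest positive double so they remain in
(0, 1]; BED scores cap −log10 p at 300.

## Profiling

* **Density filter and curves.** Per-window differences enter density
  estimation when both samples have ≥ 10 calls and max(frac_A, frac_B)
  ≥ 0.5 (windows unmethylated in both samples carry no signal). Curves are
  Gaussian KDEs with Silverman bandwidth evaluated on a fixed
  [−1, 1] × 512 grid, then renormalized by the trapezoidal integral so
  every curve integrates to exactly 1 on the grid — without this, kernel
  mass leaking past ±1 would make curves from different filters slightly
  incomparable. Windows are weighted equally, not by coverage.
* **Metaplots.** Features are aligned at the 5′ or 3′ end; minus-strand
  features are coordinate-reflected so "5′" always means the
  transcriptional start side. Flank ±3 kb, bins 100 bp (both
  parameterized). A window is assigned to the bin containing its midpoint;
  the bin value is the count-weighted pooled fraction. DMR-per-gene
  frequencies use a ≥ 1 bp overlap rule between the DMR and the bin's
  genomic interval.
* **Chromosome distribution** bins DMR midpoints into 100-kb bins (floor
  rule on boundaries). **State composition** reports the percentage of DMR
  base pairs overlapping each chromatin-state category on interval unions;
  with a full-coverage state map the percentages sum to 100, otherwise the
  remainder is reported as "unannotated". When genomic-feature categories
  are needed instead (TE / genic / intergenic), TE annotation takes
  precedence over gene on conflict, being the more specific claim.

## Imprinting analytics

Per-read assignment is a majority vote over the diagnostic SNPs the read
covers; ties and SNP-free reads are ambiguous and excluded — conservative
and deterministic. The genome-wide pooled ratio Σm/Σp is checked against
the dosage expectation (2.0 endosperm, 1.0 embryo) with a ±10% relative
tolerance by default. Gene-level comparisons keep genes with m+p ≥ 10 in
every compared sample (the threshold is exposed; "sufficient reads" has no
canonical value). The MEG/PEG class comparison is a paired t-test across
genes present in both genotypes (Welch's unpaired variant available), and a
single Pearson correlation is computed over the union of analyzed MEGs and
PEGs, mirroring how joint n = MEG + PEG correlations are reported.

## Simulator

**Genome.** Default: 3 chromosomes × 1 Mb plus a 48.5-kb unmethylated
lambda spike-in. Each chromosome is tiled with 10-kb state tiles; tiles in
the central block (20% of the chromosome) draw heterochromatic states 8–9,
the arms draw states 1–7. Genes (150/chromosome, 1–4 kb) sit in the arms;
TEs (50/chromosome, 0.3–3 kb) are 60% pericentromeric. CG site densities
are 100/kb (arms) and 120/kb (pericentromere), counting cytosines on both
strands — the scale of a CG dyad every ~20–25 bp; CHG 60/kb, CHH 150/kb.
SNPs sit on a jittered grid of one per 500 bp, emulating the density of a
polymorphic two-ecotype cross.

**DME targets.** 60 per chromosome by default: 60% placed flush against
gene boundaries in euchromatin (the gene-flanking small-TE class), 40% in
the pericentromere. Target intervals additionally carry a regular 10-bp CG
grid, making them CG-dense like the TE fragments they emulate (≥ 10 CG per
100 bp), which is what makes single planted loci statistically callable.

**Methylation model.** Baselines per (location, context): TE-like
(including targets) CG 0.90 / CHG 0.65 / CHH 0.15; heterochromatin CG
0.95 / CHG 0.70 / CHH 0.10; gene bodies CG 0.25; background CG 0.05, CHG =
CHH = 0.02. Embryo truth equals the baseline for both parents and is
identical across genotypes (maternal H1 loss leaves the embryo methylome
essentially unchanged, modeled as exactly unchanged). Endosperm: the
maternal CG genome is globally reduced by 15% (embryo CG > endosperm CG),
and maternal CG probabilities at targets drop by the demethylation depth
Δ = 0.7 from baseline. Heterochromatin targets realize only 40% of Δ in
the wild type — H1-compacted heterochromatin obstructs the glycosylase —
and the h1 genotype adds 0.42 of extra depth, capped at Δ, restoring full
demethylation. The h1 endosperm additionally gains +0.10 CG in gene bodies
(both parental genomes). These two knobs are the simulator's δ_het and
δ_gen; their arithmetic consequence is the expected signature: h1-vs-wt
endosperm differences shift negative at heterochromatin targets and
positive in gene bodies, h1 gains DMRs, and the gained DMRs are
heterochromatic.

**Expected-callable truth.** For each planted target the expected pooled
embryo-minus-endosperm difference is computed from the truth tables
themselves ((2m + p)/3 pooling for endosperm); a target is marked
expected-callable when that difference exceeds 0.35 — a margin above the
caller's 0.3 so that recovery scoring does not hinge on boundary noise.
Wild-type heterochromatin targets (expected difference ≈ 0.19) are
correctly not expected.

**Counts.** Depth per site and parent is Poisson around the parent's share
of the mean depth (default 20×): 2/3 : 1/3 for endosperm, 1/2 : 1/2 for
embryo; a negative-binomial option adds overdispersion. Observed methylated
calls are Binomial(depth, p + (1−p)·ε) with non-conversion ε = 0.01 —
failed bisulfite conversion reads out as spuriously methylated; sequencing
miscalls are not modeled. The estimator reports the spike-in rate but no
correction is applied to methylation fractions (the analysis convention).
All randomness flows from numpy's PCG64 via `SeedSequence` spawning, so
every output is a pure integer-seeded function, reproducible across
platforms.

**Expression.** 80 MEGs (maternal proportion 0.95), 42 PEGs (0.10),
remaining genes biallelic at 2/3; per gene and genotype, total reads are
Poisson(100) and maternal reads binomial. The h1 genotype shifts MEG
proportions up by 0.02 — a small maternal-ratio increase of MEGs but not
PEGs, the magnitude a paired test detects at these depths while leaving the
genotype-genotype correlation high.

**What the simulator does not emulate.** Sites are positional, not derived
from sequence, so no sequence-composition biases; no read-level artifacts
(mapping bias, PCR duplicates, M-bias); no biological replicate structure;
CHG/CHH dynamics are static per-state baselines without RdDM feedback; real
coverage is far more heterogeneous than Poisson. Passing recovery tests
therefore demonstrates the correctness and calibration of the algorithms
under the stated generative assumptions, not performance on any particular
real library.

## Test and validation sizes

The suite validates on deliberately small genomes chosen to keep thousands
of CG windows in play: a shared 2 × 200-kb scenario for caller/profiler
tests, 1 × 100 kb across 10 seeds for the null-call property (no DMRs
between two count draws from identical probabilities), and 1 × 200 kb
across 20 seeds for planted recovery (sensitivity ≥ 0.9 at Δ = 0.7 and
20×, Jaccard ≥ 0.5 per locus). The Fisher implementation is checked
exhaustively against a brute-force enumeration oracle for all 2×2 tables
with grand total ≤ 40, and against scipy on random larger tables. The
dosage check assigns ≥ 10⁵ simulated endosperm reads and requires the
pooled ratio within ±5% of 2.0.

## Known limitations

* CHG/CHH DMR calling is accepted by the engine via the context parameter
  but untuned; the DMR definition here is CG-only.
* The chromatin-state map is consumed as an input annotation; the package
  does not re-derive states.
* Lambda non-conversion is reported, never used to correct fractions.
* `welch_t` requires n ≥ 2 with non-zero variance per sample; degenerate
  inputs are errors rather than NaNs, by design.
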