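# Methods

This note documents the models, parameter choices, numerical details, and
known limitations of the `g4prom` pipeline.

## G4 sequence scoring and hit extraction

Per-base scores follow the run-length rule: a base inside a maximal run of
*k* guanines scores +min(*k*, 4), cytosine runs score −min(*k*, 4), and
A/T/U/N score 0. U is treated like T and soft-masked lowercase like
uppercase, so soft-masked genome assemblies scan identically to unmasked
ones. Window means are exact rational arithmetic on integer prefix sums.

Hit extraction collects window starts with |mean| ≥ θ (the comparison is
inclusive: "threshold 1.5" admits a window scoring exactly 1.5), groups
consecutive qualifying starts of one sign whose spacing is at most the
window length (overlapping or end-to-start adjacent windows), and never
merges across a sign change. The merged span is then refined by the minimal
deterministic rule: trim to the first and last base of the scored kind
(G for positive regions, C for negative) and recompute the mean over the
trimmed interval. Consequently a reported hit's |mean| can exceed the
qualifying window mean (e.g. a 25-mer whose windows score 64/25 reports
64/22 after trimming to its outermost Gs), and a hit can be shorter than the
window. Reverse-complement antisymmetry is exact and property-tested: C-rich
plus-strand regions are reported with strand "−", meaning the quadruplex
would form on the complementary strand.

Defaults: window 25 bp, threshold 1.5 (a conservative setting; 1.2 is the
permissive convention). The chromosome filter is exposed because genome-wide
tallies depend on whether chrY and unplaced contigs are scanned; analyses
downstream restrict to chr1–22 and X.

## Tag clustering and promoter annotation

CTSS files (chrom, 1-based position, strand, count) are unioned across
samples; duplicates within a file are summed and all-zero rows dropped.
TPM uses the per-sample total CTSS count as library size, computed before
any filtering. Clustering is single-linkage per chromosome strand: adjacent
positions p < q join one cluster iff q − p ≤ 20 (the merge distance is a
gap in bases, configurable). Cluster counts/TPM are re-quantified as sums
over member positions, so tags are conserved exactly; the peak is the member
with maximal pooled TPM, ties broken toward the cluster's 5′ end on its
strand for determinism.

Support filter: TPM strictly > 1 in at least 6 samples (half of the 12 in
the default two-condition design). The strict inequality is deliberate and
exposed as a flag, since "> 1 TPM" admits either reading at the boundary.

Annotation: a cluster survives if it shares ≥ 1 bp with an annotated TSS on
the same strand (TSS = 5′-most exon base of a transcript; Ensembl version
suffixes stripped). An optional exclusion BED (e.g. enhancer candidates from
an external caller) removes clusters strand-agnostically before this test.
Gene assignment is same-strand (antisense assignment is disallowed) against
gene spans extended 1000 bp upstream — the extension is a package choice, as
assignment windows differ between annotation toolchains — with ties broken by
TSS containment, then overlap length, then lexicographic gene id. Only
protein-coding genes on chr1–22/X are retained. The composition filter keeps
clusters contributing strictly > 10 % of their gene's summed TC activity in
≥ 6 samples; a sample where the gene has zero activity counts as failing.
After filtering, the retained fractions of a gene need not sum to 1 —
dropped clusters are excluded from testing, not re-normalized.

## Differential promoter usage

Normalization is standard TMM: M-values are log ratios of library-normalized
counts against the reference sample (the one whose 75th count-fraction
percentile is closest to the mean), trimmed 30 % per tail on M and 5 % on A,
precision-weighted, and rescaled to geometric mean 1. Because M-values are
computed on library-normalized counts, proportional columns get unit factors
(depth belongs to the library size, not the factor).

The common NB dispersion φ is a pseudo-likelihood (method-of-moments)
estimate: the φ ≥ 0 at which the pooled Pearson statistic, with group means
refit at each candidate φ, equals its pooled residual degrees of freedom;
bisection on [0, 5]. This replaces the adjusted-profile-likelihood machinery
of dedicated count packages; on NB simulations (φ = 0.05–0.1, 6+6 samples,
500+ promoters) it recovers φ within the tested tolerance band, and the
usage test's type-I error on null data calibrates to 0.03–0.07 at α = 0.05,
which is the property that matters downstream. Tagwise shrinkage is
deliberately not implemented (the ligand analysis specifies dispersions
without tagwise shrinkage; we apply the same convention throughout).

Per promoter, group rates q solve the NB score equation
Σⱼ (yⱼ − Nⱼq)/(1 + φNⱼq) = 0 by vectorized Newton iteration on log q, with
effective library sizes Nⱼ = library × TMM factor as offsets and a small
library-proportional prior count (0.125) stabilizing empty groups. The
condition logFC is log₂(q₂/q₁) with variance from the expected Fisher
information. Condition levels are ordered lexicographically, so swapping
labels exactly negates every logFC.

The usage statistic contrasts each promoter's logFC against the
inverse-variance-weighted mean of its gene's promoters; the weighted
residuals sum to zero within each gene by construction, and
Var(rel-logFC_i) = Var_i − 1/Σw. The squared standardized relative logFC is
referenced to F(1, df) with df pooled over all tested promoters (residual
df per promoter = samples − 2), which approaches the χ²₁ reference for
realistic problem sizes. Genes with a single expressed promoter are emitted
with NA statistics and excluded from the BH correction; all-zero promoters
are dropped and logged.

AP calls: BH-FDR strictly < 0.05 and |2^rel-logFC| > 2. The fold-change
threshold applies to the usage-level (relative) effect by default because
the test is usage-level; a flag thresholds the promoter-level condition
logFC instead, since the reported "|fold change| > 2" is ambiguous between
the two. The relaxed mode (unadjusted p < .05, |FC| > 1) mirrors the
weak-response reanalysis convention in the ligand branch.

Exact numerical equivalence with edgeR's diffSpliceDGE is a non-goal: the
essential statistic (promoter-vs-gene-average logFC with an F reference) is
re-implemented and validated by simulation calibration instead.

## G4 association statistics

Association: a promoter is G4-associated in a condition iff ≥ 1 peak shares
≥ 1 base (half-open arithmetic) with the promoter interval or with the
100 bp window immediately upstream. Upstream is strand-aware (rightward for
minus-strand promoters), the biologically coherent reading; a flag reverts
to strand-naive. Peaks are merged first, so the result is invariant to peak
file order and to splitting a peak into abutting pieces.

Enrichment: the 2×3 table (AP / non-AP × neither / one / both) is tested by
exact conditional enumeration — all first rows compatible with the margins,
summing probabilities ≤ the observed table's (the probability-ordering
criterion) — whenever the enumeration space is small (≤ 2×10⁶ tables, which
covers every realistic promoter set), else by seeded multivariate
hypergeometric Monte-Carlo with the add-one correction (B = 10⁵ default).
Category ratios compare proportions among APs with proportions among all
retained promoters (the background includes the APs). Empty categories are
dropped from the test; fully degenerate margins return p = 1 with a warning.

Relative density: promoters are laid out 5′→3′ (minus-strand flipped) with
unscaled flanks and bodies rescaled to a common 500 bp target, tiled in
10 bp windows. dₙ is the mean over the M regions of each window's covered
fraction, i.e. Σᵢwᵢ/(10·M), which is bounded in [0, 1] and exactly additive
under M-weighted pooling of disjoint promoter sets. The literal variant
dividing by 10·N (N = number of windows) is also computed and reported
side-by-side; it is not a per-window coverage fraction (it scales with M/N)
and is retained only for comparability, since published formulations differ
on this denominator.

Signal: base-weighted means over promoter intervals from bedGraph (or
BigWig, when pyBigWig is installed); uncovered bases count 0, absent contigs
warn and yield 0. One-tailed Wilcoxon–Mann–Whitney comparisons use the exact
null for small untied samples.

Directionality: per AP, the G4 effect is *promoting* if the promoter is
G4-associated only in its more-active condition, *repressing* if only in the
less-active one, *neutral* if both or neither (the both-conditions case is
deliberately neutral; its tie-breaking is otherwise unspecifiable). Gene
patterns: *promotes*/*represses* require a single AP direction and no
opposite effects; *bidirectional_promotes*/*_represses* require APs up in
both directions with ≥ 1 consistent effect in each; everything else —
including genes whose APs carry only neutral effects — is *mixed* and
excluded from pattern counts.

## Ligand branch

Transcripts sharing a TSS form one promoter (exact-position grouping; a
first-exon-overlap mode is configurable). A promoter's count is the sum of
unique junction reads over the distinct first introns of its transcripts;
single-exon transcripts contribute nothing, and a promoter whose first exon
lies entirely within an internal (non-first) exon of another transcript of
the same gene is flagged internal and excluded. Junctions with STAR strand
code 0 are used only when they match exactly one gene; unmatched junction
reads are counted in the log so reads in = reads counted + reads unmatched.
The CPM > 1 (strict) in ≥ 1 sample filter recomputes library sizes on the
retained rows. Nearest-G4 distance is interval-to-hit-edge (0 on overlap;
TSS-point mode available), strand-ignored; the random baseline draws
|AP set| promoters uniformly without replacement from the expressed non-AP
pool under the supplied seed (an expression-matched draw is not implemented
and would be the natural extension).

## Synthetic data generator

The generator emulates the statistical structure of a two-condition 5′-end
profiling comparison at desk scale: 200 non-overlapping genes on one
chromosome, 87.7 % with a single promoter and the rest with 2–4 (spacing
600 bp), two-exon transcripts so every promoter has a distinct first
intron; 6 replicates per condition; CTSS counts NB-distributed
(gamma-Poisson, φ = 0.05) around a mean of depth (200) × gene factor
(log-normal, σ = 0.5) × usage share, spread multinomially over ±3 bp of the
TSS with fixed triangular weights; a gene-level condition factor
(log-normal, σ = 0.2) plants expression changes that are *not* usage
changes, exercising the test's invariance to them.

Planted switches: a fraction (0.3) of multi-promoter genes get one target
promoter whose share moves 4-fold (0.4 → 0.1 of gene output), the others
absorbing the complement so their own usage change stays below the 2-fold
threshold — the planted truth is therefore one AP per switched gene with a
known direction. G4 peaks (±30 bp around the TSS) are planted at the target
promoter in its up-condition with probability ρ (default 0.8) and at any
promoter in both conditions at a background rate (0.1); matching G4
sequence motifs (a 22-mer of four G₄ tracts, reverse-complemented on minus
strands) are written into the genome at every peak, plus 50 background
motifs rejection-sampled away from existing sites, and generation asserts
the scanner recovers each one at default parameters. Junction tables reuse
the same usage shares with an independent expression draw.

Randomness is split into named substreams spawned from the master seed
(counts, genome, layout, peaks, junctions, signal), so outputs are
byte-identical per (config, seed) and adding one output kind does not
perturb the others.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: promoter shape (sharp vs broad), overlapping
and antisense genes, enhancer contamination of 5′-end signal, mappability
and blacklist artefacts, realistic peak width/score distributions,
expression-matched G4 placement, or tagwise dispersion heterogeneity.
Recovery rates on synthetic data are upper bounds.

## Problem sizes and numerical choices

Test-suite simulations use 200–800 genes and 6+6 samples; the calibration
check uses ≥ 2000 tested promoters and the coupling check 10 seeds × 3
coupling levels — sizes chosen so the full suite runs in well under a
minute per statistical check while leaving the binomial noise on the
asserted quantities small relative to the asserted bands. Newton iterations
for the NB rate run to |Δ| < 10⁻¹² (≤ 50 steps, step-clipped at ±5);
bisection for φ to 10⁻⁶; Var(rel-logFC) is floored at 10⁻¹² before forming
the statistic; peak ties, gene-assignment ties and cluster ids are all
resolved by fixed deterministic rules stated above.

## Limitations

- The usage test is a two-condition contrast; multi-condition designs and
  gene-level aggregation (e.g. Simes) are out of scope.
- Common dispersion only; strong per-promoter dispersion heterogeneity will
  mis-calibrate individual promoters even though the global error rate
  holds.
- De-novo promoters are excluded by construction (TSS-overlap filter), and
  enhancer detection is delegated to an external exclusion BED.
- Genome-scale scans are sequential per chromosome; an hg19 scan is
  minutes-scale, not interactive.
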