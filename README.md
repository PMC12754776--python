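# g4prom

Tools for asking whether **G-quadruplex (G4) structures** shape **alternative
promoter (AP) usage**. Many human genes carry several promoters; which one a
cell uses determines the transcript isoform it makes. G4s — four-stranded DNA
structures formed by stacked guanine tetrads in G-rich sequence — are enriched
at promoters and correlate with transcriptional activity, which raises the
question this package operationalizes: *are the promoters whose relative usage
differs between two cellular conditions preferentially associated with G4s,
and does the condition-specific presence of a G4 track with the direction of
the usage change?*

The package implements the full analysis as a tested library
(`src/g4prom/`), a set of numbered analysis drivers (`analysis/`), and a CLI
(`g4prom`), all exercisable without any external download through a bundled
synthetic-data generator with known ground truth.

## What it computes

**G4 prediction (`g4scan`).** G4Hunter-style scoring: each base in a maximal
run of *k* guanines scores +min(*k*, 4); cytosine runs score the negated
values; A/T/U/N are neutral. A sliding window (default *W* = 25 bp) is
thresholded at |mean| ≥ θ (default 1.5, a conservative setting); qualifying
windows of one sign are merged, trimmed to the outermost scored base, and
reported as candidate G4 regions. A negative mean marks a C-rich region, so
the quadruplex forms on the complementary strand — one plus-strand scan
covers both strands.

**Promoter calling (`tssclust`, `annot`).** CAGE-style 5′-end counts (CTSS)
are normalized to tags-per-million TPMᵢⱼ = cᵢⱼ/Nⱼ·10⁶, pooled, and
single-linkage clustered with a 20 bp merge distance into strand-specific tag
clusters (TCs ≈ promoters). Filters: activity > 1 TPM in ≥ 6 of 12 samples;
overlap with an annotated TSS on the same strand; assignment to a
protein-coding gene on chr1–22/X; contribution > 10 % of the gene's promoter
activity in ≥ 6 samples.

**Differential usage (`diffusage`).** TMM-normalized promoter counts are fit
per promoter with an NB GLM (log link, offsets = log effective library size,
common dispersion φ̂ from a pooled Pearson moment estimator). The
diffSplice-style statistic contrasts each promoter's condition log₂FC against
the inverse-variance-weighted mean log₂FC of its gene,

  rel-logFC_i = logFC_i − (Σ wₖ logFCₖ)/(Σ wₖ),  wₖ = 1/Var(logFCₖ),

so gene-level expression changes cancel and only *usage* changes remain.
APs are promoters with BH-FDR < 0.05 and |fold change| > 2; genes with one
expressed promoter are excluded.

**G4 association (`g4assoc`).** A promoter is G4-associated in a condition if
≥ 1 G4 ChIP-seq peak overlaps it or the 100 bp immediately upstream
(strand-aware). APs vs all promoters are compared across the
neither/one/both-condition categories with an exact 2×3 Fisher test
(full conditional enumeration, seeded Monte-Carlo fallback); relative G4
density dₙ = Σᵢ wᵢ/(10·M) is profiled in 10 bp windows around scaled
promoter bodies; ΔG4 signal and one-tailed Wilcoxon rank-sum comparisons
quantify condition-specific intensity; and each gene's APs are classified as
G4 *promotes* / *represses* / *bidirectional* / *mixed*.

**Ligand branch (`ligand`).** Promoter activity is quantified from
splice-junction tables (unique reads over the distinct first introns of the
transcripts sharing a TSS; single-exon transcripts and internal promoters
excluded), filtered at CPM > 1, tested with the same machinery (a relaxed
p < .05, |FC| > 1 mode exists for weak responses), and AP-to-nearest-G4
distances are compared against a seeded random promoter baseline.

**Synthetic data (`synth`).** Generates genome, GTF, CTSS, peaks, signal and
junction files with planted usage switches (target promoter moving 4-fold,
e.g. 40 % → 10 % of gene output), G4 peaks coupled to the switched promoter's
up-condition with probability ρ, and matching sequence motifs — all
byte-reproducible from a seed, with truth tables for recall scoring.

## Worked example

```bash
cd analysis
python 01_simulate_world.py && python 04_diff_usage.py && python 05_g4_association.py
```

prints (seed 11, default configuration):

```
Differential promoter usage (condB vs condA):
  phi_hat: 0.053
  promoters_tested: 89
  aps_called: 11
  recall: 0.9
  direction_accuracy: 1.0
G4 association statistics:
  fisher_p: 5.39e-14
  ap_fraction_g4_associated: 0.8182
  directionality_counts: {'promotes': 7, 'mixed': 2}
  peak_density_max_window: up_20
```

Reading: of 89 testable promoters, 11 are called APs, recovering 9/10 planted
switches with the correct direction; the AP set is strongly enriched for
promoters with a condition-specific G4 peak (the planted coupling, ρ = 0.8),
G4 density peaks immediately upstream of APs, and the per-gene pattern is
dominated by "G4 promotes", as designed. Driver 06 adds the junction-based
branch (median AP-to-G4 distance 31 bp vs 725 bp for random promoters).

Real data plug in the same way: CTSS text files, a GENCODE-dialect GTF, peak
BEDs and bedGraph/BigWig signal, and STAR-style `SJ.out.tab` junction tables
(`g4prom run-all --config cfg.yaml`, or the library functions directly). A
genome-wide scan of an hg19 FASTA (`g4prom scan --fasta hg19.fa`) reproduces
the full predicted-G4 catalogue but needs the external genome download.

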