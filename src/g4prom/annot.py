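"""Restrict tag clusters to annotated promoters of protein-coding genes.

Three successive filters mirror a conventional CAGE promoter-annotation
workflow: (1) keep clusters that share >= 1 bp with an annotated TSS on the
same strand (optionally removing clusters in a user-supplied exclusion set,
e.g. enhancer candidates); (2) assign each cluster to a same-strand gene and
keep only protein-coding genes on the 22 autosomes plus X; (3) keep clusters
contributing > 10% of their gene's total promoter activity in at least six
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from . import io as g4io
from .tssclust import TagCluster

DEFAULT_UPSTREAM_EXTENSION = 1000
DEFAULT_MIN_FRACTION = 0.10
DEFAULT_MIN_SAMPLES = 6
ALLOWED_CHROMS = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X"])


@dataclass
class GeneModel:
    """One gene with its transcript structures and per-transcript TSSs."""

    gene_id: str                   # Ensembl, version stripped
    symbol: str
    chrom: str
    strand: str
    span: tuple[int, int]          # 0-based half-open gene span
    biotype: str
    tss_set: list[int]             # 1-based TSS positions, one per transcript
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # transcript_id -> exons as 0-based half-open spans, sorted by coordinate

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.span[0], self.span[1], self.strand)


def _strip_version(identifier: str) -> str:
    return identifier.split(".")[0]


def transcript_tss(exons: list[tuple[int, int]], strand: str) -> int:
    """1-based TSS: 5'-most exon base on the transcript strand."""
    if strand == "+":
        return min(e[0] for e in exons) + 1
    return max(e[1] for e in exons)


def parse_gene_models(gtf_path) -> list[GeneModel]:
    """Build gene models from a GENCODE-dialect GTF.

    The TSS of a transcript is its 5'-most exon base; Ensembl version
    suffixes are stripped from gene and transcript IDs.
    """
    gtf = g4io.read_gtf(gtf_path)
    exons = gtf[gtf["feature"] == "exon"]
    if exons.empty:
        raise ValueError(f"no exon features in {gtf_path}")
    tx_meta: dict[str, dict] = {}
    for row in exons.itertuples():
        tx = _strip_version(row.transcript_id)
        meta = tx_meta.setdefault(tx, {"gene_id": _strip_version(row.gene_id),
                                       "chrom": row.chrom, "strand": row.strand,
                                       "exons": []})
        if meta["gene_id"] != _strip_version(row.gene_id):
            raise ValueError(f"transcript {tx} assigned to multiple genes")
        meta["exons"].append((row.start, row.end))

    gene_rows = gtf[gtf["feature"] == "gene"]
    gene_attrs = {}
    for row in gene_rows.itertuples():
        gid = _strip_version(row.gene_id)
        if gid in gene_attrs:
            raise ValueError(f"duplicated gene feature for {gid}")
        gene_attrs[gid] = {"biotype": row.gene_type or "", "symbol": row.gene_name or "",
                           "span": (row.start, row.end)}

    genes: dict[str, GeneModel] = {}
    for tx, meta in tx_meta.items():
        gid = meta["gene_id"]
        exon_list = sorted(meta["exons"])
        attrs = gene_attrs.get(gid, {})
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid, symbol=attrs.get("symbol", ""), chrom=meta["chrom"],
                strand=meta["strand"], span=attrs.get("span", (exon_list[0][0],
                                                               exon_list[-1][1])),
                biotype=attrs.get("biotype", ""), tss_set=[], transcripts={},
            )
        gene = genes[gid]
        if tx in gene.transcripts:
            raise ValueError(f"duplicated transcript id {tx}")
        gene.transcripts[tx] = exon_list
        gene.tss_set.append(transcript_tss(exon_list, meta["strand"]))
        lo = min(gene.span[0], exon_list[0][0])
        hi = max(gene.span[1], exon_list[-1][1])
        gene.span = (lo, hi)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.span[0], g.gene_id))


def _overlaps_any(tc: TagCluster, intervals: pd.DataFrame) -> bool:
    sub = intervals[intervals["chrom"] == tc.interval.chrom]
    return bool(((sub["start"] < tc.interval.end) & (sub["end"] > tc.interval.start)).any())


def tss_overlap_filter(tcs: list[TagCluster], models: list[GeneModel],
                       exclusion_bed=None) -> list[TagCluster]:
    """Keep clusters that overlap >= 1 annotated TSS on the same strand.

    Clusters overlapping any exclusion interval (strand-ignored) are dropped
    first, regardless of TSS support.
    """
    exclusion = g4io.read_bed(exclusion_bed) if exclusion_bed is not None else None
    tss_by_key: dict[tuple[str, str], np.ndarray] = {}
    for g in models:
        for pos in g.tss_set:
            tss_by_key.setdefault((g.chrom, g.strand), []).append(pos)
    tss_by_key = {k: np.unique(np.asarray(v)) for k, v in tss_by_key.items()}
    kept = []
    for tc in tcs:
        if exclusion is not None and _overlaps_any(tc, exclusion):
            continue
        positions = tss_by_key.get((tc.interval.chrom, tc.interval.strand))
        if positions is None:
            continue
        # TSS position p (1-based) occupies [p-1, p); overlap with [start, end)
        lo = np.searchsorted(positions, tc.interval.start + 1)
        hi = np.searchsorted(positions, tc.interval.end, side="right")
        if hi > lo:
            kept.append(tc)
    return kept


def assign_genes(tcs: list[TagCluster], models: list[GeneModel],
                 upstream: int = DEFAULT_UPSTREAM_EXTENSION,
                 allowed_chroms: tuple[str, ...] = ALLOWED_CHROMS,
                 protein_coding_only: bool = True) -> list[TagCluster]:
    """Assign each cluster to a same-strand gene; unassignable clusters are dropped.

    A gene is a candidate when its span, extended `upstream` bp on its 5' side,
    overlaps the cluster.  Ties prefer the gene with a TSS inside the cluster,
    then the largest overlap, then the lexicographically smallest gene_id.
    Only protein-coding genes on the allowed chromosomes survive.
    """
    candidates = [g for g in models
                  if (not protein_coding_only or g.biotype == "protein_coding")
                  and g.chrom in allowed_chroms]
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in candidates:
        by_key.setdefault((g.chrom, g.strand), []).append(g)
    out = []
    for tc in tcs:
        if tc.interval.chrom not in allowed_chroms:
            continue
        scored = []
        for g in by_key.get((tc.interval.chrom, tc.interval.strand), []):
            lo, hi = g.span
            if g.strand == "+":
                lo = max(0, lo - upstream)
            else:
                hi = hi + upstream
            if not (lo < tc.interval.end and tc.interval.start < hi):
                continue
            has_tss = any(tc.interval.start < p <= tc.interval.end for p in g.tss_set)
            overlap = min(hi, tc.interval.end) - max(lo, tc.interval.start)
            scored.append((-int(has_tss), -overlap, g.gene_id, g))
        if scored:
            # prefer TSS-containing, then larger overlap, then smallest gene_id
            _, _, _, gene = min(scored)
            tc.gene_id = gene.gene_id
            tc.symbol = gene.symbol
            out.append(tc)
    return out


def composition_filter(tcs: list[TagCluster], min_fraction: float = DEFAULT_MIN_FRACTION,
                       min_samples: int = DEFAULT_MIN_SAMPLES) -> list[TagCluster]:
    """Keep clusters whose share of their gene's activity is strictly greater
    than `min_fraction` in at least `min_samples` samples.

    A sample in which the gene has zero total activity counts as "not passing"
    for all of that gene's clusters.
    """
    by_gene: dict[str, list[TagCluster]] = {}
    for tc in tcs:
        if tc.gene_id is None:
            raise ValueError(f"cluster {tc.id} lacks a gene assignment")
        by_gene.setdefault(tc.gene_id, []).append(tc)
    kept = []
    for members in by_gene.values():
        totals = np.sum([tc.tpm_per_sample for tc in members], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            for tc in members:
                frac = np.where(totals > 0, tc.tpm_per_sample / np.where(totals > 0,
                                                                         totals, 1.0), 0.0)
                if int((frac > min_fraction).sum()) >= min_samples:
                    kept.append(tc)
    kept.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.id))
    return kept
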