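"""G4-ligand branch: promoter activity from splice junctions and AP detection.

RNA-seq splice junctions (STAR-style tables, 1-based inclusive intron
coordinates) are converted to promoter-level counts: transcripts sharing a
TSS form one promoter, whose count in a sample is the sum of unique reads
over the distinct first introns of its transcripts.  Single-exon transcripts
contribute nothing; promoters whose first exon lies entirely inside an
internal exon of another transcript of the same gene are flagged internal
and excluded.  After a CPM > 1 filter the differential-usage machinery of
:mod:`g4prom.diffusage` is applied (strict FDR mode, or a relaxed
unadjusted-p mode for weak responses), and AP-to-nearest-G4 distances are
compared with a seeded random promoter baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffusage
from . import io as g4io
from .annot import GeneModel

DEFAULT_MIN_CPM = 1.0
STRAND_CODE = {0: ".", 1: "+", 2: "-"}


@dataclass
class PromoterAnnotation:
    """Junction-level annotation of one promoter (gene + shared TSS)."""

    promoter_id: str
    gene_id: str
    chrom: str
    strand: str
    tss_position: int                       # 1-based
    first_exon: tuple[int, int]             # 0-based half-open, 5'-most exon
    first_introns: list[tuple[int, int]]    # 1-based inclusive intron coords
    internal: bool


def _first_intron(exons: list[tuple[int, int]], strand: str) -> tuple[int, int]:
    """1-based inclusive coordinates of the transcript's 5'-most intron."""
    if strand == "+":
        e1, e2 = exons[0], exons[1]
    else:
        e1, e2 = exons[-1], exons[-2]
        e1, e2 = e2, e1  # genomic left-to-right
    return e1[1] + 1, e2[0]


def build_promoter_annotation(models: list[GeneModel]) -> list[PromoterAnnotation]:
    """Group transcripts into promoters by shared TSS and flag internal ones."""
    promoters: list[PromoterAnnotation] = []
    for gene in models:
        internal_exons: list[tuple[int, int]] = []
        for exons in gene.transcripts.values():
            if len(exons) < 2:
                continue
            first = exons[0] if gene.strand == "+" else exons[-1]
            internal_exons.extend(e for e in exons if e != first)
        by_tss: dict[int, dict] = {}
        for tx, exons in gene.transcripts.items():
            if len(exons) < 2:  # single-exon transcripts are excluded
                continue
            tss = exons[0][0] + 1 if gene.strand == "+" else exons[-1][1]
            first = exons[0] if gene.strand == "+" else exons[-1]
            entry = by_tss.setdefault(tss, {"first_exon": first, "introns": set()})
            entry["introns"].add(_first_intron(exons, gene.strand))
        for rank, tss in enumerate(sorted(by_tss), start=1):
            entry = by_tss[tss]
            fe = entry["first_exon"]
            internal = any(ie[0] <= fe[0] and fe[1] <= ie[1] for ie in internal_exons)
            promoters.append(PromoterAnnotation(
                promoter_id=f"{gene.gene_id}:p{rank}", gene_id=gene.gene_id,
                chrom=gene.chrom, strand=gene.strand, tss_position=tss,
                first_exon=fe, first_introns=sorted(entry["introns"]),
                internal=internal))
    return promoters


def junctions_to_promoter_counts(junction_files: list, models: list[GeneModel],
                                 sample_ids: list[str] | None = None,
                                 drop_internal: bool = True
                                 ) -> tuple[pd.DataFrame, dict]:
    """Promoter x sample count matrix from splice-junction tables.

    Returns (counts frame, log).  The frame carries promoter_id, gene_id,
    chrom, strand, tss_position, internal flag and one integer column per
    sample; the log records the unique reads of junctions matching no
    annotated first intron (per sample), so that reads in = reads counted +
    reads unmatched.
    """
    if sample_ids is None:
        sample_ids = [str(p) for p in junction_files]
    promoters = build_promoter_annotation(models)
    intron_index: dict[tuple, list[int]] = {}
    for i, p in enumerate(promoters):
        for intron in p.first_introns:
            intron_index.setdefault((p.chrom, intron[0], intron[1], p.strand), []).append(i)
    counts = np.zeros((len(promoters), len(sample_ids)), dtype=np.int64)
    unmatched = {}
    for j, path in enumerate(junction_files):
        sj = g4io.read_sj(path)
        lost = 0
        for row in sj.itertuples():
            strand = STRAND_CODE[row.strand_code]
            if strand == ".":
                hits = (intron_index.get((row.chrom, row.intron_start, row.intron_end, "+"), [])
                        + intron_index.get((row.chrom, row.intron_start, row.intron_end, "-"), []))
                genes = {promoters[i].gene_id for i in hits}
                if len(genes) != 1:  # ambiguous undefined-strand junction
                    lost += row.unique_reads
                    continue
            else:
                hits = intron_index.get((row.chrom, row.intron_start, row.intron_end, strand), [])
            if not hits:
                lost += row.unique_reads
                continue
            for i in hits:
                counts[i, j] += row.unique_reads
        unmatched[sample_ids[j]] = int(lost)
    meta = pd.DataFrame({
        "promoter_id": [p.promoter_id for p in promoters],
        "gene_id": [p.gene_id for p in promoters],
        "chrom": [p.chrom for p in promoters],
        "strand": [p.strand for p in promoters],
        "tss_position": [p.tss_position for p in promoters],
        "internal": [p.internal for p in promoters],
    })
    for j, s in enumerate(sample_ids):
        meta[s] = counts[:, j]
    if drop_internal:
        meta = meta[~meta["internal"]].reset_index(drop=True)
    log = {"unmatched_unique_reads": unmatched,
           "n_internal_promoters": int(sum(p.internal for p in promoters))}
    return meta, log


def cpm_filter(counts: pd.DataFrame, sample_ids: list[str],
               min_cpm: float = DEFAULT_MIN_CPM, min_samples: int = 1
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Keep promoters with CPM strictly > min_cpm in >= min_samples samples.

    Library sizes are recomputed on the retained rows and returned.
    """
    mat = counts[sample_ids].to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero library size")
    cpm = mat / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    filtered = counts[keep].reset_index(drop=True)
    new_lib = filtered[sample_ids].to_numpy(dtype=float).sum(axis=0)
    return filtered, new_lib


def ligand_diff_usage(counts: pd.DataFrame, sample_ids: list[str], groups,
                      mode: str = "strict") -> pd.DataFrame:
    """Differential promoter usage for the ligand experiment.

    Strict mode: FDR < 0.05 and |fold change| > 2.  Relaxed mode (for weak
    responses): unadjusted p < .05 and |fold change| > 1.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    res = diffusage.diff_usage_test(
        counts[sample_ids].to_numpy(dtype=float),
        counts["promoter_id"].to_numpy(), counts["gene_id"].to_numpy(), groups)
    if mode == "strict":
        return diffusage.call_aps(res, alpha=0.05, fc_min=2.0, use_fdr=True)
    return diffusage.call_aps(res, alpha=0.05, fc_min=1.0, use_fdr=False)


# ---------------------------------------------------------------------------
# nearest-G4 distances

def _distances(promoters: pd.DataFrame, g4_by_chrom: dict[str, np.ndarray],
               mode: str) -> np.ndarray:
    out = np.empty(len(promoters))
    for k, row in enumerate(promoters.itertuples()):
        iv = g4_by_chrom.get(row.chrom)
        if iv is None or len(iv) == 0:
            out[k] = np.inf
            continue
        if mode == "point":
            a = b = row.tss_position - 1
            b = a + 1
        else:
            a, b = row.start, row.end
        i = int(np.searchsorted(iv[:, 1], a, side="right"))
        if i < len(iv) and iv[i, 0] < b:
            out[k] = 0.0
            continue
        gaps = []
        if i < len(iv):
            gaps.append(iv[i, 0] - b)
        if i > 0:
            gaps.append(a - iv[i - 1, 1])
        out[k] = float(min(gaps))
    return out


def nearest_g4_distance(ap_promoters: pd.DataFrame, g4_hits: pd.DataFrame,
                        background_promoters: pd.DataFrame,
                        n_random: int | None = None, seed: int = 0,
                        mode: str = "interval") -> dict:
    """Distances from APs (and a seeded random promoter sample) to the nearest
    predicted G4, with a one-tailed rank-sum test that AP distances are smaller.

    Distance is 0 for overlap, else the gap in bases to the nearest hit edge
    on the same chromosome (strand-ignored).  `mode="point"` measures from
    the TSS base instead of the promoter interval.  Promoters on chromosomes
    without any hit are excluded with a warning.
    """
    from .g4assoc import merge_intervals
    g4_by_chrom = merge_intervals(g4_hits)
    if n_random is None:
        n_random = len(ap_promoters)
    rng = np.random.default_rng(seed)
    pool = background_promoters.reset_index(drop=True)
    if len(pool) < n_random:
        raise ValueError("background smaller than requested random sample")
    pick = rng.choice(len(pool), size=n_random, replace=False)
    random_set = pool.iloc[np.sort(pick)]

    d_ap = _distances(ap_promoters, g4_by_chrom, mode)
    d_rand = _distances(random_set, g4_by_chrom, mode)
    for name, d in (("AP", d_ap), ("random", d_rand)):
        if np.isinf(d).any():
            import warnings
            warnings.warn(f"{int(np.isinf(d).sum())} {name} promoters on chromosomes "
                          "without G4 hits excluded")
    d_ap, d_rand = d_ap[np.isfinite(d_ap)], d_rand[np.isfinite(d_rand)]
    from .g4assoc import rank_sum_one_tailed
    p = rank_sum_one_tailed(d_rand, d_ap)  # random stochastically larger <=> APs closer
    return {"distances_ap": d_ap, "distances_random": d_rand, "p_one_tailed": p,
            "n_ap": int(len(d_ap)), "n_random": int(len(d_rand))}
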