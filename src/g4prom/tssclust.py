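"""CAGE-style tag clustering: from per-base CTSS counts to promoter candidates.

CTSS tracks from several samples are unioned into a position x sample count
matrix, normalized to tags-per-million (TPM), pooled, and single-linkage
clustered on each chromosome strand with a 20 bp merge distance.  Clusters
are requantified (counts and TPM summed over member positions) and filtered
for support (> 1 TPM in at least half of the samples by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, one_based_pos_to_interval
from . import io as g4io

DEFAULT_MERGE_DIST = 20
DEFAULT_MIN_TPM = 1.0
DEFAULT_MIN_SAMPLES = 6


@dataclass
class CtssMatrix:
    """Union of CTSS positions across samples with an integer count matrix."""

    positions: pd.DataFrame  # columns: chrom, pos (1-based), strand
    counts: np.ndarray       # positions x samples
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError("counts shape does not match positions x samples")
        if (self.counts < 0).any():
            raise ValueError("negative CTSS counts")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class TagCluster:
    """A strand-specific cluster of nearby CTSS positions (promoter candidate)."""

    interval: GenomicInterval
    peak_position: int              # 1-based position of maximal pooled TPM
    counts_per_sample: np.ndarray
    tpm_per_sample: np.ndarray
    id: str
    gene_id: str | None = None
    symbol: str | None = None
    member_positions: list[int] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand


def read_ctss(paths: list, sample_ids: list[str] | None = None) -> CtssMatrix:
    """Read CTSS files into one matrix; positions absent from a sample count 0.

    Duplicate (chrom, pos, strand) rows within one file are summed; rows that
    are zero in every sample are dropped.
    """
    if sample_ids is None:
        sample_ids = [str(p) for p in paths]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids must match paths")
    per_sample = []
    for path in paths:
        df = g4io.read_ctss_file(path)
        df = df.groupby(["chrom", "pos", "strand"], as_index=True)["count"].sum()
        per_sample.append(df)
    mat = pd.concat(per_sample, axis=1, keys=sample_ids).fillna(0).astype(np.int64)
    mat = mat[(mat.sum(axis=1) > 0)]
    mat = mat.sort_index()
    positions = mat.index.to_frame(index=False, name=["chrom", "pos", "strand"])
    return CtssMatrix(positions, mat.to_numpy(), list(sample_ids))


def tpm_normalize(m: CtssMatrix) -> tuple[np.ndarray, np.ndarray]:
    """TPM[i, j] = counts[i, j] / library_size(j) * 1e6; pooled = row sum of TPM."""
    lib = m.counts.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"zero library size for sample {m.sample_ids[zero[0]]!r}")
    tpm = m.counts / lib * 1e6
    return tpm, tpm.sum(axis=1)


def call_tag_clusters(m: CtssMatrix, merge_dist: int = DEFAULT_MERGE_DIST) -> list[TagCluster]:
    """Single-linkage clustering of CTSS positions per chromosome strand.

    Adjacent member positions p < q join one cluster iff q - p <= merge_dist.
    Counts and TPM are requantified as sums over member positions; the peak is
    the member with maximal pooled TPM, ties broken toward the cluster's 5'
    end on its strand.
    """
    if merge_dist < 0:
        raise ValueError("merge_dist must be >= 0")
    tpm, pooled = tpm_normalize(m)
    pos = m.positions
    clusters: list[TagCluster] = []
    order = np.lexsort((pos["pos"].to_numpy(), pos["strand"].to_numpy(),
                        pos["chrom"].to_numpy()))
    chrom_a, pos_a, strand_a = (pos["chrom"].to_numpy()[order],
                                pos["pos"].to_numpy()[order],
                                pos["strand"].to_numpy()[order])
    group_change = np.flatnonzero((chrom_a[1:] != chrom_a[:-1])
                                  | (strand_a[1:] != strand_a[:-1])
                                  | (np.diff(pos_a) > merge_dist)) + 1
    for rows in np.split(order, group_change):
        positions = pos["pos"].to_numpy()[rows]
        chrom = pos["chrom"].to_numpy()[rows][0]
        strand = pos["strand"].to_numpy()[rows][0]
        start0, _ = one_based_pos_to_interval(int(positions.min()))
        end0 = int(positions.max())
        pooled_members = pooled[rows]
        best = pooled_members.max()
        tied = positions[pooled_members == best]
        peak = int(tied.min()) if strand == "+" else int(tied.max())
        clusters.append(TagCluster(
            interval=GenomicInterval(chrom, start0, end0, strand),
            peak_position=peak,
            counts_per_sample=m.counts[rows].sum(axis=0),
            tpm_per_sample=tpm[rows].sum(axis=0),
            id="",
            member_positions=[int(p) for p in sorted(positions)],
        ))
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.strand))
    for i, c in enumerate(clusters):
        c.id = f"TC_{i + 1:05d}"
    return clusters


def support_filter(tcs: list[TagCluster], min_tpm: float = DEFAULT_MIN_TPM,
                   min_samples: int = DEFAULT_MIN_SAMPLES) -> list[TagCluster]:
    """Keep clusters with TPM strictly > min_tpm in at least min_samples samples."""
    if tcs and min_samples > len(tcs[0].tpm_per_sample):
        raise ValueError("min_samples exceeds the number of samples")
    return [tc for tc in tcs if int((tc.tpm_per_sample > min_tpm).sum()) >= min_samples]


def clusters_to_frame(tcs: list[TagCluster], sample_ids: list[str]) -> pd.DataFrame:
    """Flatten clusters to a table: BED-like columns + per-sample counts/TPM."""
    rows = []
    for tc in tcs:
        row = {
            "id": tc.id, "chrom": tc.interval.chrom, "start": tc.interval.start,
            "end": tc.interval.end, "strand": tc.interval.strand,
            "peak_pos": tc.peak_position, "gene_id": tc.gene_id, "symbol": tc.symbol,
        }
        for s, c, t in zip(sample_ids, tc.counts_per_sample, tc.tpm_per_sample):
            row[f"count_{s}"] = int(c)
            row[f"tpm_{s}"] = float(t)
        rows.append(row)
    return pd.DataFrame(rows)
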