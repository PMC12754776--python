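"""Readers and writers for the text formats the pipeline consumes and emits.

Formats: FASTA (via pyfaidx), BED6, bedGraph, BigWig (optional, via pyBigWig
if installed), GENCODE-dialect GTF, 4-column CTSS text and 9-column
STAR-style splice-junction tables.  All parse errors name the file, the line
number, and the offending field.  Coordinates are converted to the internal
0-based half-open convention through :mod:`g4prom.intervals` only.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import one_based_span_to_zero

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    pass


def _fail(path, lineno: int, msg: str):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame with the BED6 columns (missing -> defaults)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                _fail(path, lineno, f"expected >=3 BED fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}")
            if not (0 <= start < end):
                _fail(path, lineno, f"invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                _fail(path, lineno, f"invalid strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, score_decimals: int = 3) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out = out[BED_COLUMNS]
    out["score"] = out["score"].map(lambda v: f"{v:.{score_decimals}f}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph / BigWig signal

class SignalTrack:
    """Piecewise-constant genome signal with O(log n) interval means.

    Backed by per-chromosome sorted, non-overlapping intervals with a prefix
    sum of ``value * width`` so that the base-weighted mean over any query
    interval is two binary searches.  Bases not covered by any record
    contribute 0.
    """

    def __init__(self, frames: dict[str, pd.DataFrame]):
        self._data = {}
        for chrom, df in frames.items():
            df = df.sort_values("start", kind="stable")
            starts = df["start"].to_numpy(dtype=np.int64)
            ends = df["end"].to_numpy(dtype=np.int64)
            vals = df["value"].to_numpy(dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ParseError(f"overlapping bedGraph records on {chrom}")
            csum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
            self._data[chrom] = (starts, ends, vals, csum)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def _covered_sum(self, chrom: str, a: int, b: int) -> float:
        starts, ends, vals, csum = self._data[chrom]
        lo = int(np.searchsorted(ends, a, side="right"))
        hi = int(np.searchsorted(starts, b, side="left"))
        if lo >= hi:
            return 0.0
        total = csum[hi] - csum[lo]
        # trim partial overlap at both edges
        if starts[lo] < a:
            total -= vals[lo] * (a - starts[lo])
        if ends[hi - 1] > b:
            total -= vals[hi - 1] * (ends[hi - 1] - b)
        return float(total)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Base-weighted mean signal over [start, end); absent contig -> 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._data:
            return 0.0
        return self._covered_sum(chrom, start, end) / (end - start)


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 bedGraph fields, got {len(fields)}")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                _fail(path, lineno, f"malformed record {fields!r}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_signal(path) -> SignalTrack:
    """Load a signal track from bedGraph, or BigWig when pyBigWig is available."""
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        try:
            import pyBigWig
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("BigWig input requires the optional pyBigWig dependency") from exc
        bw = pyBigWig.open(str(path))
        frames = {}
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if ivs:
                frames[chrom] = pd.DataFrame(ivs, columns=["start", "end", "value"])
        bw.close()
        return SignalTrack(frames)
    df = read_bedgraph(path)
    return SignalTrack({c: g for c, g in df.groupby("chrom")})


# ---------------------------------------------------------------------------
# GTF (GENCODE dialect)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

GTF_REQUIRED_ATTRS = {"gene": ("gene_id",), "transcript": ("gene_id", "transcript_id"),
                      "exon": ("gene_id", "transcript_id")}


def read_gtf(path, features: Sequence[str] = ("gene", "transcript", "exon")) -> pd.DataFrame:
    """Parse GTF features into a flat table with internal 0-based coordinates.

    Columns: chrom, source, feature, start, end (half-open), strand, plus the
    attributes gene_id, transcript_id, gene_type, gene_name when present.
    """
    wanted = set(features)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                _fail(path, lineno, f"expected 9 GTF fields, got {len(fields)}")
            feature = fields[2]
            if feature not in wanted:
                continue
            try:
                start0, end0 = one_based_span_to_zero(int(fields[3]), int(fields[4]))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
            strand = fields[6]
            if strand not in ("+", "-"):
                _fail(path, lineno, f"invalid strand {strand!r}")
            attrs = dict(_ATTR_RE.findall(fields[8]))
            for req in GTF_REQUIRED_ATTRS.get(feature, ()):
                if req not in attrs:
                    _fail(path, lineno, f"{feature} feature missing attribute {req!r}")
            rows.append((fields[0], fields[1], feature, start0, end0, strand,
                         attrs.get("gene_id"), attrs.get("transcript_id"),
                         attrs.get("gene_type"), attrs.get("gene_name")))
    return pd.DataFrame(rows, columns=["chrom", "source", "feature", "start", "end",
                                       "strand", "gene_id", "transcript_id",
                                       "gene_type", "gene_name"])


# ---------------------------------------------------------------------------
# CTSS (chrom, 1-based position, strand, count)

def read_ctss_file(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 CTSS fields, got {len(fields)}")
            chrom, pos_s, strand, count_s = fields
            if strand not in ("+", "-"):
                _fail(path, lineno, f"invalid strand {strand!r}")
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError:
                _fail(path, lineno, f"non-integer position/count {pos_s!r}/{count_s!r}")
            if pos < 1:
                _fail(path, lineno, f"position must be >= 1, got {pos}")
            if count < 0:
                _fail(path, lineno, f"count must be >= 0, got {count}")
            rows.append((chrom, pos, strand, count))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


def write_ctss(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "strand", "count"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# STAR SJ.out.tab (9 columns)

SJ_COLUMNS = ["chrom", "intron_start", "intron_end", "strand_code", "motif",
              "annotated", "unique_reads", "multi_reads", "overhang"]


def read_sj(path) -> pd.DataFrame:
    """Read a STAR-style splice-junction table (1-based inclusive intron coords)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 9:
                _fail(path, lineno, f"expected 9 SJ fields, got {len(fields)}")
            try:
                vals = [fields[0]] + [int(x) for x in fields[1:]]
            except ValueError:
                _fail(path, lineno, f"non-integer SJ field in {fields!r}")
            if vals[3] not in (0, 1, 2):
                _fail(path, lineno, f"strand code must be 0/1/2, got {vals[3]}")
            if vals[1] > vals[2]:
                _fail(path, lineno, f"intron start {vals[1]} > end {vals[2]}")
            if vals[6] < 0:
                _fail(path, lineno, f"unique read count must be >= 0, got {vals[6]}")
            rows.append(vals)
    return pd.DataFrame(rows, columns=SJ_COLUMNS)


def write_sj(df: pd.DataFrame, path) -> None:
    df[SJ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
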