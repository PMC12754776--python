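"""Association of promoters with G4 peaks, and the derived statistics.

A promoter is G4-associated in a condition when at least one G4 ChIP-seq
peak shares >= 1 base with the promoter interval or with the 100 bp window
immediately upstream of it (strand-aware by default).  From the per-condition
flags each promoter falls in one of three categories - G4 in neither, one,
or both conditions - and the module computes: a 2x3 Fisher exact enrichment
of alternative promoters (APs) across categories, relative G4 density
profiles around promoters (10 bp windows, bodies scaled to a common width),
mean G4 ChIP-seq signal per promoter with one-tailed rank-sum comparisons,
and a per-gene classification of the direction of the G4 effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf, log

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_UPSTREAM = 100
DEFAULT_DENSITY_WIDTH = 10
DEFAULT_BODY_TARGET = 500
CATEGORIES = ("neither", "one", "both")
PATTERNS = ("promotes", "represses", "bidirectional_promotes",
            "bidirectional_represses", "mixed")


# ---------------------------------------------------------------------------
# interval machinery

def merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome merged, sorted (n, 2) interval arrays from a BED frame."""
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
        iv = iv[np.argsort(iv[:, 0], kind="stable")]
        merged = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _any_overlap(merged: dict[str, np.ndarray], chrom: str, start: int, end: int) -> bool:
    iv = merged.get(chrom)
    if iv is None or len(iv) == 0:
        return False
    i = int(np.searchsorted(iv[:, 1], start, side="right"))
    return i < len(iv) and iv[i, 0] < end


def _covered_bases(iv: np.ndarray, csum: np.ndarray, a: int, b: int) -> int:
    """Bases of [a, b) covered by merged intervals iv (with coverage prefix sums)."""
    if b <= a or len(iv) == 0:
        return 0
    lo = int(np.searchsorted(iv[:, 1], a, side="right"))
    hi = int(np.searchsorted(iv[:, 0], b, side="left"))
    if lo >= hi:
        return 0
    total = csum[hi] - csum[lo]
    if iv[lo, 0] < a:
        total -= a - iv[lo, 0]
    if iv[hi - 1, 1] > b:
        total -= iv[hi - 1, 1] - b
    return int(total)


# ---------------------------------------------------------------------------
# association

@dataclass
class AssociationRecord:
    promoter_id: str
    gene_id: str | None
    assoc: dict[str, bool]
    category: str
    delta_signal: float | None = None
    is_ap: bool = False


def upstream_window(start: int, end: int, strand: str, upstream: int) -> tuple[int, int]:
    """Strand-aware window of `upstream` bases immediately 5' of [start, end)."""
    if strand == "-":
        return end, end + upstream
    return max(0, start - upstream), start


def associate_g4(promoters: pd.DataFrame, peaks: dict[str, pd.DataFrame],
                 upstream: int = DEFAULT_UPSTREAM,
                 strand_aware: bool = True) -> pd.DataFrame:
    """Flag each promoter as G4-associated per condition and derive its category.

    `promoters` needs columns id, chrom, start, end, strand; `peaks` maps a
    condition name to a BED frame of (unstranded) peak intervals.  A promoter
    is associated when a peak overlaps its interval or its upstream window
    (half-open arithmetic, >= 1 shared base).  With `strand_aware=False`
    the upstream window is always taken to the left.
    """
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    merged = {cond: merge_intervals(df) for cond, df in peaks.items()}
    out = promoters[["id", "chrom", "start", "end", "strand"]].copy()
    if "gene_id" in promoters.columns:
        out["gene_id"] = promoters["gene_id"].to_numpy()
    for cond, m in merged.items():
        flags = []
        for row in out.itertuples():
            strand = row.strand if strand_aware else "+"
            ua, ub = upstream_window(row.start, row.end, strand, upstream)
            lo = min(row.start, ua) if ub > ua else row.start
            hi = max(row.end, ub) if ub > ua else row.end
            flags.append(_any_overlap(m, row.chrom, lo, hi))
        out[f"assoc_{cond}"] = flags
    conds = list(peaks)
    n_assoc = sum(out[f"assoc_{c}"].astype(int) for c in conds)
    if len(conds) == 2:
        out["category"] = np.select([n_assoc == 0, n_assoc == 1], ["neither", "one"], "both")
    out["n_assoc"] = n_assoc
    return out


# ---------------------------------------------------------------------------
# 2 x c Fisher exact enrichment

def fisher_exact_2xc(table: np.ndarray, max_exact_tables: int = 2_000_000,
                     n_mc: int = 100_000, seed: int = 0) -> float:
    """Exact conditional p for a 2 x c table (probability-ordering criterion).

    Enumerates all first rows compatible with the margins when that space is
    small enough, summing the multivariate hypergeometric probabilities of
    tables no more probable than the observed one; otherwise falls back to a
    seeded Monte-Carlo estimate with the add-one correction.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x c table")
    table = table[:, table.sum(axis=0) > 0]  # empty categories carry no information
    col = table.sum(axis=0)
    r1 = int(table[0].sum())
    n = int(table.sum())
    if r1 == 0 or r1 == n or table.shape[1] < 2:
        import warnings
        warnings.warn("degenerate contingency margin; p = 1")
        return 1.0

    def log_prob(row1: np.ndarray) -> float:
        return sum(log(comb(int(c), int(a))) for c, a in zip(col, row1)) - log(comb(n, r1))

    lp_obs = log_prob(table[0])
    space = np.prod([min(r1, int(c)) + 1 for c in col])
    if space <= max_exact_tables:
        total = 0.0
        # enumerate the free cells of row 1 (last cell is determined)
        def recurse(j: int, remaining: int, row: list[int]):
            nonlocal total
            if j == len(col) - 1:
                if 0 <= remaining <= col[j]:
                    lp = log_prob(np.asarray(row + [remaining]))
                    if lp <= lp_obs + 1e-9:
                        total += np.exp(lp)
                return
            for a in range(0, min(remaining, int(col[j])) + 1):
                recurse(j + 1, remaining - a, row + [a])
        recurse(0, r1, [])
        return float(min(total, 1.0))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col, r1, size=n_mc)
    lps = np.array([log_prob(d) for d in draws])
    return float((np.sum(lps <= lp_obs + 1e-9) + 1) / (n_mc + 1))


def category_enrichment(records: pd.DataFrame, ap_mask,
                        seed: int = 0, n_mc: int = 100_000) -> dict:
    """AP-vs-background enrichment of G4 categories (2 x 3 Fisher exact).

    `records` is the association table for all retained promoters (the
    background); `ap_mask` flags the AP subset.  The contingency rows are
    AP / non-AP; ratios compare category proportions among APs with the
    proportions among the full background.
    """
    ap_mask = np.asarray(ap_mask, dtype=bool)
    cats = pd.Categorical(records["category"], categories=list(CATEGORIES))
    tab = pd.crosstab(ap_mask, cats, dropna=False)
    tab = tab.reindex([True, False], fill_value=0).reindex(columns=list(CATEGORIES),
                                                           fill_value=0)
    table = np.vstack([tab.loc[True].to_numpy(), tab.loc[False].to_numpy()])
    p = fisher_exact_2xc(table, seed=seed, n_mc=n_mc)
    ap_prop = table[0] / max(table[0].sum(), 1)
    bg_prop = (table[0] + table[1]) / max(table.sum(), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bg_prop > 0, ap_prop / bg_prop, np.nan)
    return {
        "table": {cat: {"ap": int(table[0, i]), "non_ap": int(table[1, i])}
                  for i, cat in enumerate(CATEGORIES)},
        "fisher_p": p,
        "ratios": {cat: float(ratios[i]) for i, cat in enumerate(CATEGORIES)},
    }


# ---------------------------------------------------------------------------
# relative density

@dataclass
class DensityProfile:
    window_width: int
    flank: int
    values: np.ndarray          # per-region-normalized coverage fraction, in [0, 1]
    values_printed: np.ndarray  # literal sum(w_i) / (width * N) variant
    m_regions: int
    n_windows: int
    labels: list[str]


def relative_density(promoters: pd.DataFrame, g4_intervals: pd.DataFrame,
                     width: int = DEFAULT_DENSITY_WIDTH, flank: int = 500,
                     body_target: int = DEFAULT_BODY_TARGET) -> DensityProfile:
    """G4 coverage density in fixed windows around promoters.

    Each promoter contributes `flank/width` upstream windows, `body_target/
    width` windows over its body rescaled to a common length, and the
    downstream flank; minus-strand promoters are flipped so 5'->3' reads left
    to right.  d_n is the mean over regions of the per-window coverage
    fraction, i.e. sum_i w_i / (width * M); the literal width * N denominator
    is also reported for comparison.
    """
    for name, val in (("flank", flank), ("body_target", body_target)):
        if val % width != 0:
            raise ValueError(f"{name} must be a multiple of the window width")
    merged = merge_intervals(g4_intervals)
    csums = {c: np.concatenate([[0], np.cumsum(iv[:, 1] - iv[:, 0])])
             for c, iv in merged.items()}
    nf, nb = flank // width, body_target // width
    n_windows = 2 * nf + nb
    m = len(promoters)
    if m == 0:
        raise ValueError("no promoter regions")
    acc = np.zeros(n_windows)
    for row in promoters.itertuples():
        iv = merged.get(row.chrom, np.empty((0, 2), dtype=np.int64))
        cs = csums.get(row.chrom, np.array([0]))
        left_edges = row.start + np.arange(-nf, 1) * width
        right_edges = row.end + np.arange(0, nf + 1) * width
        body_edges = np.rint(np.linspace(row.start, row.end, nb + 1)).astype(np.int64)
        fracs = []
        for edges in (left_edges, body_edges, right_edges):
            for a, b in zip(edges[:-1], edges[1:]):
                if b <= a:  # degenerate scaled window for tiny bodies
                    a2, b2 = a, a + 1
                else:
                    a2, b2 = a, b
                fracs.append(_covered_bases(iv, cs, int(max(a2, 0)), int(b2))
                             / (b2 - a2))
        fracs = np.asarray(fracs)
        if row.strand == "-":
            fracs = fracs[::-1]
        acc += fracs
    values = acc / m
    labels = ([f"up_{(nf - i) * width}" for i in range(nf)]
              + [f"body_{i + 1}" for i in range(nb)]
              + [f"down_{(i + 1) * width}" for i in range(nf)])
    # literal denominator variant: sum_i w_i / (width * N) == values * M / N
    return DensityProfile(width, flank, values, values * (m / n_windows),
                          m, n_windows, labels)


# ---------------------------------------------------------------------------
# signal

def signal_at_promoters(promoters: pd.DataFrame, tracks: dict) -> pd.DataFrame:
    """Base-weighted mean signal per promoter per condition track, plus delta.

    `tracks` maps condition name to a SignalTrack; `delta_signal` is the
    first-listed condition minus the second.
    """
    out = promoters[["id", "chrom", "start", "end", "strand"]].copy()
    conds = list(tracks)
    for cond, track in tracks.items():
        out[f"mean_{cond}"] = [track.mean(r.chrom, r.start, r.end)
                               for r in promoters.itertuples()]
    if len(conds) == 2:
        out["delta_signal"] = out[f"mean_{conds[0]}"] - out[f"mean_{conds[1]}"]
    return out


def rank_sum_one_tailed(greater_group, other_group) -> float:
    """One-tailed Wilcoxon-Mann-Whitney p that `greater_group` is stochastically
    larger than `other_group` (exact for small untied samples)."""
    x = np.asarray(greater_group, dtype=float)
    y = np.asarray(other_group, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    method = "exact" if (len(x) <= 20 and len(y) <= 20
                         and len(np.unique(np.r_[x, y])) == len(x) + len(y)) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


# ---------------------------------------------------------------------------
# directionality

@dataclass
class DirectionalityCall:
    gene_id: str
    pattern: str


def _ap_effect(direction_up: str, assoc: dict[str, bool], cond_names: tuple[str, str]) -> str:
    """Effect of G4 on one AP: promoting when the G4 is present only in the
    condition where the promoter is more active, repressing when only in the
    other, neutral when in both or neither."""
    a, b = cond_names
    up = {f"up_{a}": a, f"up_{b}": b}.get(direction_up)
    if up is None:
        raise ValueError(f"unknown direction label {direction_up!r}")
    down = b if up == a else a
    if assoc[up] and not assoc[down]:
        return "promoting"
    if assoc[down] and not assoc[up]:
        return "repressing"
    return "neutral"


def classify_directionality(ap_table: pd.DataFrame,
                            cond_names: tuple[str, str]) -> list[DirectionalityCall]:
    """Per-gene pattern of the G4 effect over that gene's APs.

    `ap_table` needs columns gene_id, direction (up_<cond>), and
    assoc_<cond> for both conditions.  Genes whose APs move in a single
    direction with only promoting (or only repressing) G4 effects are
    classified accordingly; genes with APs up in both directions and
    consistent effects are "bidirectional_*"; anything else is "mixed"
    (excluded from pattern counts downstream).
    """
    a, b = cond_names
    calls = []
    for gene_id, sub in ap_table.groupby("gene_id", sort=True):
        effects, directions = [], set()
        for row in sub.itertuples():
            assoc = {a: getattr(row, f"assoc_{a}"), b: getattr(row, f"assoc_{b}")}
            effects.append(_ap_effect(row.direction, assoc, (a, b)))
            directions.add(row.direction)
        n_prom = effects.count("promoting")
        n_rep = effects.count("repressing")
        single = len(directions) == 1
        if single and n_prom >= 1 and n_rep == 0:
            pattern = "promotes"
        elif single and n_rep >= 1 and n_prom == 0:
            pattern = "represses"
        elif len(directions) == 2 and n_rep == 0 and n_prom >= 1 and _each_direction(
                sub, effects, "promoting"):
            pattern = "bidirectional_promotes"
        elif len(directions) == 2 and n_prom == 0 and n_rep >= 1 and _each_direction(
                sub, effects, "repressing"):
            pattern = "bidirectional_represses"
        else:
            pattern = "mixed"
        calls.append(DirectionalityCall(str(gene_id), pattern))
    return calls


def _each_direction(sub: pd.DataFrame, effects: list[str], wanted: str) -> bool:
    """True iff every AP direction present in the gene has >= 1 AP with the
    wanted G4 effect."""
    by_dir: dict[str, bool] = {}
    for direction, effect in zip(sub["direction"], effects):
        by_dir[direction] = by_dir.get(direction, False) or effect == wanted
    return all(by_dir.values())
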