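"""Synthetic genomes, CTSS tracks, peaks, signal, and junction tables with
known ground truth.

The generator emulates the statistical structure of a two-cell-line
NET-CAGE / G4 ChIP-seq comparison: multi-promoter protein-coding genes on a
random genome, negative-binomially distributed CTSS counts spread over a few
bases around each TSS, planted promoter-usage switches between the two
conditions, G4 peaks coupled to condition-up promoters with a configurable
probability rho, matching G4 sequence motifs planted in the genome, and
splice-junction tables consistent with the same usage shares.  Every output
is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import g4scan
from . import io as g4io

CTSS_OFFSETS = np.arange(-3, 4)
CTSS_WEIGHTS = np.array([1, 3, 6, 10, 6, 3, 1], dtype=float)
CTSS_WEIGHTS /= CTSS_WEIGHTS.sum()

DEFAULT_G4_MOTIF = "GGGGTTGGGGTTGGGGTTGGGG"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SynthConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_genes: int = 200
    single_promoter_prob: float = 0.877   # observed fraction of single-promoter genes
    max_promoters: int = 4
    n_samples: int = 6                    # replicates per condition
    conditions: tuple[str, str] = ("condA", "condB")
    depth: float = 200.0                  # mean tags per promoter per sample
    nb_dispersion: float = 0.05
    switch_fraction: float = 0.3          # of multi-promoter genes with a planted switch
    switch_effect: float = 4.0            # usage fold change of the switched promoter
    g4_coupling: float = 0.8              # P(condition-specific peak at the switched promoter)
    g4_background_rate: float = 0.10      # P(shared peak at any promoter)
    gene_log_sd: float = 0.5              # lognormal spread of gene expression
    gene_condition_sd: float = 0.2        # gene-level (non-usage) condition effect
    chrom: str = "chr1"
    promoter_spacing: int = 600
    first_exon_len: int = 150
    intron_len: int = 400
    last_exon_len: int = 200
    intergenic_gap: int = 800
    g4_motif: str = DEFAULT_G4_MOTIF
    n_intergenic_motifs: int = 50

    def validate(self) -> None:
        for name in ("single_promoter_prob", "switch_fraction", "g4_coupling",
                     "g4_background_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1 or self.max_promoters < 1 or self.n_samples < 1:
            raise ValueError("n_genes, max_promoters and n_samples must be >= 1")
        if self.depth <= 0 or self.nb_dispersion < 0 or self.switch_effect <= 1:
            raise ValueError("depth > 0, nb_dispersion >= 0, switch_effect > 1 required")


# ---------------------------------------------------------------------------
# building blocks

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) via gamma-Poisson; Poisson when phi == 0."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def draw_promoter_numbers(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    n = np.where(rng.random(cfg.n_genes) < cfg.single_promoter_prob, 1, 0)
    multi = rng.integers(2, cfg.max_promoters + 1, size=cfg.n_genes)
    return np.where(n == 1, 1, multi)


def draw_usage_shares(rng: np.random.Generator, cfg: SynthConfig,
                      n_promoters: np.ndarray) -> pd.DataFrame:
    """Per-promoter usage shares in both conditions, with planted switches.

    A switched gene has one target promoter whose share moves f-fold between
    conditions (f = switch_effect), from s_hi = f/(2(f+1)) down to
    s_lo = 1/(2(f+1)) (0.4 -> 0.1 at the default f = 4); the other promoters
    absorb the complement equally, so their own usage change stays below the
    2-fold AP threshold and the gene's AP signal is single-directional, as
    in a promoter switch driven by one regulated promoter.  Unswitched genes
    keep one Dirichlet share vector in both conditions.
    """
    rows = []
    f = cfg.switch_effect
    s_hi, s_lo = 0.5 * f / (f + 1), 0.5 / (f + 1)
    cond_a, cond_b = cfg.conditions
    for g, k in enumerate(n_promoters):
        gene_id = f"ENSGS{g + 1:05d}"
        switched = k >= 2 and rng.random() < cfg.switch_fraction
        if switched:
            target = int(rng.integers(k))
            up_cond = cond_a if rng.random() < 0.5 else cond_b
            share_up = np.full(k, (1 - s_hi) / (k - 1))
            share_up[target] = s_hi
            share_dn = np.full(k, (1 - s_lo) / (k - 1))
            share_dn[target] = s_lo
            sa, sb = (share_up, share_dn) if up_cond == cond_a else (share_dn, share_up)
        else:
            target = -1
            shares = rng.dirichlet(np.full(k, 8.0))
            sa = sb = shares
        for p in range(k):
            lfc = float(np.log2(sb[p] / sa[p]))
            planted = switched and p == target
            rows.append({
                "gene_id": gene_id, "promoter_id": f"{gene_id}:p{p + 1}",
                "promoter_rank": p + 1, "n_promoters": int(k),
                "share_condA": float(sa[p]), "share_condB": float(sb[p]),
                "is_switch_gene": bool(switched), "is_switch_target": planted,
                "is_planted_ap": planted,
                "usage_log2fc": lfc,
                "direction": ("" if not planted
                              else (f"up_{cond_b}" if lfc > 0 else f"up_{cond_a}")),
            })
    return pd.DataFrame(rows)


def simulate_usage_counts(cfg: SynthConfig, rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Promoter x sample NB count matrix plus truth table and group labels.

    This is the count-level core used both directly (for statistical
    calibration at scale) and by :func:`simulate_world` (which spreads the
    same totals over genomic CTSS positions).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_prom = draw_promoter_numbers(rng, cfg)
    truth = draw_usage_shares(rng, cfg, n_prom)
    expr = rng.lognormal(0.0, cfg.gene_log_sd, size=cfg.n_genes)
    condfac = rng.lognormal(0.0, cfg.gene_condition_sd, size=cfg.n_genes)
    gene_index = truth["gene_id"].str.slice(5).astype(int).to_numpy() - 1
    shares = truth[["share_condA", "share_condB"]].to_numpy()
    groups = np.array([cfg.conditions[0]] * cfg.n_samples
                      + [cfg.conditions[1]] * cfg.n_samples)
    counts = np.zeros((len(truth), 2 * cfg.n_samples), dtype=np.int64)
    for j, cond in enumerate(groups):
        ci = 0 if cond == cfg.conditions[0] else 1
        mean = cfg.depth * expr[gene_index] * shares[:, ci]
        if ci == 1:
            mean = mean * condfac[gene_index]
        counts[:, j] = _nb_draw(rng, mean, cfg.nb_dispersion)
    return counts, truth, groups


# ---------------------------------------------------------------------------
# world generation

@dataclass
class GeneLayout:
    gene_id: str
    strand: str
    tss_positions: list[int]         # 0-based first-exon starts... see build
    first_exons: list[tuple[int, int]]
    second_exon: tuple[int, int]
    span: tuple[int, int]


def _layout_genes(cfg: SynthConfig, n_prom: np.ndarray,
                  rng: np.random.Generator) -> tuple[list[GeneLayout], int]:
    layouts = []
    cursor = cfg.intergenic_gap
    for g, k in enumerate(n_prom):
        gene_id = f"ENSGS{g + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(k)
        width_promoters = (k - 1) * cfg.promoter_spacing + cfg.first_exon_len
        if strand == "+":
            first_exons = [(cursor + p * cfg.promoter_spacing,
                            cursor + p * cfg.promoter_spacing + cfg.first_exon_len)
                           for p in range(k)]
            sx = cursor + width_promoters + cfg.intron_len
            second_exon = (sx, sx + cfg.last_exon_len)
            span = (cursor, second_exon[1])
        else:
            second_exon = (cursor, cursor + cfg.last_exon_len)
            fe0 = cursor + cfg.last_exon_len + cfg.intron_len
            # promoter rank p is 5'->3' on the minus strand: rightmost first
            first_exons = [(fe0 + (k - 1 - p) * cfg.promoter_spacing,
                            fe0 + (k - 1 - p) * cfg.promoter_spacing + cfg.first_exon_len)
                           for p in range(k)]
            span = (cursor, max(e[1] for e in first_exons))
        layouts.append(GeneLayout(gene_id, strand, [], first_exons, second_exon, span))
        cursor = span[1] + cfg.intergenic_gap
    return layouts, cursor


def _tss_of(layout: GeneLayout, p: int) -> int:
    """1-based TSS of promoter rank p (0-based index)."""
    fe = layout.first_exons[p]
    return fe[0] + 1 if layout.strand == "+" else fe[1]


def _write_gtf(cfg: SynthConfig, layouts: list[GeneLayout], path) -> None:
    lines = []
    for lay in layouts:
        exons_all = [e for e in lay.first_exons] + [lay.second_exon]
        g1, g2 = min(e[0] for e in exons_all) + 1, max(e[1] for e in exons_all)
        attrs_gene = (f'gene_id "{lay.gene_id}.1"; gene_type "protein_coding"; '
                      f'gene_name "SYN{lay.gene_id[-5:]}";')
        lines.append(f"{cfg.chrom}\tsynth\tgene\t{g1}\t{g2}\t.\t{lay.strand}\t.\t{attrs_gene}")
        for p, fe in enumerate(lay.first_exons):
            tx = f"{lay.gene_id}T{p + 1}.1"
            exons = sorted([fe, lay.second_exon])
            t1, t2 = exons[0][0] + 1, exons[-1][1]
            attrs = (f'gene_id "{lay.gene_id}.1"; transcript_id "{tx}"; '
                     f'gene_type "protein_coding"; gene_name "SYN{lay.gene_id[-5:]}";')
            lines.append(f"{cfg.chrom}\tsynth\ttranscript\t{t1}\t{t2}\t.\t{lay.strand}\t.\t{attrs}")
            for e in exons:
                lines.append(f"{cfg.chrom}\tsynth\texon\t{e[0] + 1}\t{e[1]}\t.\t{lay.strand}\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_world(cfg: SynthConfig, out_dir) -> dict:
    """Generate every pipeline input with ground truth under `out_dir`.

    Returns a manifest dict naming all written files plus the truth tables.
    Generation asserts that every planted G4 motif is recovered by the
    scanner at default parameters.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_counts = np.random.default_rng(streams[0])
    rng_genome = np.random.default_rng(streams[1])
    rng_layout = np.random.default_rng(streams[2])
    rng_peaks = np.random.default_rng(streams[3])
    rng_sj = np.random.default_rng(streams[4])
    rng_signal = np.random.default_rng(streams[5])

    counts, truth, groups = simulate_usage_counts(cfg, rng_counts)
    n_prom = truth.groupby("gene_id", sort=True)["promoter_rank"].max().to_numpy()
    layouts, genome_len = _layout_genes(cfg, n_prom, rng_layout)

    # genome background
    genome = rng_genome.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                               size=genome_len + cfg.intergenic_gap)

    # --- peaks, coupled motifs
    truth = truth.copy()
    truth["chrom"] = cfg.chrom
    tss, strands = [], []
    lay_by_gene = {l.gene_id: l for l in layouts}
    for row in truth.itertuples():
        lay = lay_by_gene[row.gene_id]
        tss.append(_tss_of(lay, row.promoter_rank - 1))
        strands.append(lay.strand)
    truth["tss"] = tss
    truth["strand"] = strands

    cond_a, cond_b = cfg.conditions
    peaks: dict[str, list[tuple[int, int]]] = {cond_a: [], cond_b: []}
    motif_sites: list[tuple[int, str]] = []  # (0-based start, strand)
    g4_flags = {cond_a: np.zeros(len(truth), dtype=bool),
                cond_b: np.zeros(len(truth), dtype=bool)}
    for i, row in enumerate(truth.itertuples()):
        tss0 = row.tss - 1
        peak = (max(0, tss0 - 30), tss0 + 30)
        planted = False
        if row.is_switch_target and row.direction:
            up = row.direction.removeprefix("up_")
            if rng_peaks.random() < cfg.g4_coupling:
                peaks[up].append(peak)
                g4_flags[up][i] = True
                planted = True
        if rng_peaks.random() < cfg.g4_background_rate:
            peaks[cond_a].append(peak)
            peaks[cond_b].append(peak)
            g4_flags[cond_a][i] = g4_flags[cond_b][i] = True
            planted = True
        if planted:
            offset = 60 if row.strand == "+" else -40
            motif_sites.append((tss0 - offset, row.strand))
    # extra motifs for the random-promoter distance baseline; rejection-sample
    # away from already-planted sites so no motif clobbers another
    taken = sorted(s for s, _ in motif_sites)
    for _ in range(cfg.n_intergenic_motifs):
        for _try in range(100):
            pos = int(rng_peaks.integers(0, len(genome) - len(cfg.g4_motif) - 1))
            if all(abs(pos - t) > 2 * len(cfg.g4_motif) for t in taken):
                break
        taken.append(pos)
        motif_sites.append((pos, "+"))

    for start, strand in motif_sites:
        motif = cfg.g4_motif if strand == "+" else revcomp(cfg.g4_motif)
        genome[start:start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)

    truth["g4_condA"] = g4_flags[cond_a]
    truth["g4_condB"] = g4_flags[cond_b]
    genome_str = genome.tobytes().decode()

    # planted motifs must be recovered by the scanner at default parameters
    for start, strand in motif_sites:
        a = max(0, start - 30)
        b = min(len(genome_str), start + len(cfg.g4_motif) + 30)
        hits = g4scan.extract_hits(genome_str[a:b])
        assert any(h.interval.start + a < start + len(cfg.g4_motif)
                   and start < h.interval.end + a
                   for h in hits), "planted G4 motif not recovered"

    manifest: dict = {"files": {}, "config": dataclasses.asdict(cfg)}
    fasta_path = out / "genome.fa"
    g4io.write_fasta([(cfg.chrom, genome_str)], fasta_path)
    gtf_path = out / "genes.gtf"
    _write_gtf(cfg, layouts, gtf_path)
    manifest["files"]["fasta"] = str(fasta_path)
    manifest["files"]["gtf"] = str(gtf_path)

    # --- CTSS tracks: spread each promoter/sample total over +-3 bp
    sample_ids = [f"{c}_rep{r + 1}" for c in cfg.conditions for r in range(cfg.n_samples)]
    ctss_dir = out / "ctss"
    ctss_dir.mkdir(exist_ok=True)
    ctss_paths = []
    for j, sid in enumerate(sample_ids):
        recs: dict[tuple[str, int, str], int] = {}
        for i, row in enumerate(truth.itertuples()):
            total = int(counts[i, j])
            if total == 0:
                continue
            split = rng_counts.multinomial(total, CTSS_WEIGHTS)
            for off, c in zip(CTSS_OFFSETS, split):
                if c > 0:
                    pos = row.tss + int(off)
                    key = (cfg.chrom, pos, row.strand)
                    recs[key] = recs.get(key, 0) + int(c)
        df = pd.DataFrame([(k[0], k[1], k[2], v) for k, v in sorted(recs.items())],
                          columns=["chrom", "pos", "strand", "count"])
        path = ctss_dir / f"{sid}.ctss"
        g4io.write_ctss(df, path)
        ctss_paths.append(str(path))
    manifest["files"]["ctss"] = ctss_paths
    manifest["sample_ids"] = sample_ids
    manifest["groups"] = [g for g in groups]

    # --- peaks + signal per condition
    for cond in cfg.conditions:
        iv = sorted(set(peaks[cond]))
        bed = pd.DataFrame(iv, columns=["start", "end"])
        bed.insert(0, "chrom", cfg.chrom)
        bed["name"] = [f"peak_{cond}_{i + 1}" for i in range(len(bed))]
        bed["score"] = 0.0
        bed["strand"] = "."
        path = out / f"peaks_{cond}.bed"
        g4io.write_bed(bed, path)
        manifest["files"][f"peaks_{cond}"] = str(path)
        # signal: constant-height blocks over merged peaks
        from .g4assoc import merge_intervals
        merged = merge_intervals(bed) if len(bed) else {}
        rows = []
        for chrom, arr in merged.items():
            for s, e in arr:
                rows.append((chrom, int(s), int(e),
                             float(np.round(10.0 + rng_signal.normal(0, 1), 4))))
        sig = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        spath = out / f"signal_{cond}.bedgraph"
        g4io.write_bedgraph(sig, spath)
        manifest["files"][f"signal_{cond}"] = str(spath)

    # --- splice junction tables consistent with the same usage shares
    sj_dir = out / "sj"
    sj_dir.mkdir(exist_ok=True)
    sj_paths = []
    intron_of = {}
    for lay in layouts:
        for p, fe in enumerate(lay.first_exons):
            if lay.strand == "+":
                intron = (fe[1] + 1, lay.second_exon[0])
            else:
                intron = (lay.second_exon[1] + 1, fe[0])
            intron_of[f"{lay.gene_id}:p{p + 1}"] = (intron, lay.strand)
    gene_index = truth["gene_id"].str.slice(5).astype(int).to_numpy() - 1
    expr_sj = rng_sj.lognormal(0.0, cfg.gene_log_sd, size=cfg.n_genes)
    for j, sid in enumerate(sample_ids):
        ci = 0 if groups[j] == cfg.conditions[0] else 1
        share = truth["share_condA" if ci == 0 else "share_condB"].to_numpy()
        mean = cfg.depth * expr_sj[gene_index] * share
        reads = _nb_draw(rng_sj, mean, cfg.nb_dispersion)
        rows = []
        for i, row in enumerate(truth.itertuples()):
            (a, b), strand = intron_of[row.promoter_id]
            rows.append((cfg.chrom, a, b, 1 if strand == "+" else 2, 0, 1,
                         int(reads[i]), 0, 30))
        sj = pd.DataFrame(sorted(rows), columns=g4io.SJ_COLUMNS)
        path = sj_dir / f"{sid}_SJ.out.tab"
        g4io.write_sj(sj, path)
        sj_paths.append(str(path))
    manifest["files"]["sj"] = sj_paths

    truth_path = out / "truth_promoters.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    manifest["files"]["truth_promoters"] = str(truth_path)
    genes = (truth.groupby("gene_id", sort=True)
             .agg(n_promoters=("promoter_rank", "max"),
                  switched=("is_switch_gene", "any")).reset_index())
    genes_path = out / "truth_genes.tsv"
    genes.to_csv(genes_path, sep="\t", index=False)
    manifest["files"]["truth_genes"] = str(genes_path)
    (out / "config.json").write_text(json.dumps(manifest["config"], indent=2,
                                                default=str) + "\n")
    manifest["counts"] = counts
    manifest["truth"] = truth
    return manifest


# ---------------------------------------------------------------------------
# truth comparison

def match_clusters_to_truth(tc_frame: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Map tag clusters to truth promoters: a cluster matches the truth
    promoter whose TSS falls inside it on the same chromosome and strand."""
    rows = []
    for t in truth.itertuples():
        hit = tc_frame[(tc_frame["chrom"] == t.chrom)
                       & (tc_frame["strand"] == t.strand)
                       & (tc_frame["start"] < t.tss)
                       & (tc_frame["end"] >= t.tss)]
        rows.append({"promoter_id": t.promoter_id,
                     "tc_id": hit["id"].iloc[0] if len(hit) else None})
    return pd.DataFrame(rows)


def truth_recall(ap_results: pd.DataFrame, truth: pd.DataFrame,
                 id_map: pd.DataFrame | None = None) -> dict:
    """Recall/precision of planted APs and direction accuracy of recovered ones.

    `ap_results` must carry promoter_id (or tc_id resolvable through
    `id_map`), is_ap, and direction; `truth` carries is_planted_ap and
    direction per planted promoter.
    """
    res = ap_results.copy()
    if id_map is not None:
        # results are keyed by cluster id; translate to truth promoter ids
        res = res.merge(id_map.dropna(), left_on="promoter_id", right_on="tc_id",
                        how="inner", suffixes=("_tc", ""))
    merged = truth.merge(res[["promoter_id", "is_ap", "direction"]],
                         on="promoter_id", how="left",
                         suffixes=("_truth", ""))
    if merged["is_ap"].isna().all() and len(res):
        raise ValueError("identifier mismatch between results and truth")
    merged["is_ap"] = merged["is_ap"].astype("boolean").fillna(False).astype(bool)
    planted = merged[merged["is_planted_ap"]]
    called = merged[merged["is_ap"].astype(bool)]
    recovered = planted[planted["is_ap"].astype(bool)]
    recall = len(recovered) / len(planted) if len(planted) else float("nan")
    precision = (float((called["is_planted_ap"]).mean())
                 if len(called) else float("nan"))
    direction_acc = (float((recovered["direction"] == recovered["direction_truth"]).mean())
                     if len(recovered) else float("nan"))
    return {"recall": recall, "precision": precision,
            "direction_accuracy": direction_acc,
            "n_planted": int(len(planted)), "n_called": int(len(called))}
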