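"""Junction-derived promoter counts, the ligand AP branch, and G4 distances."""

import numpy as np
import pandas as pd
import pytest

from g4prom import annot, ligand
from g4prom.io import BED_COLUMNS

from conftest import write_lines


def gene(gene_id, strand, transcripts, chrom="chr1"):
    tss = [annot.transcript_tss(ex, strand) for ex in transcripts.values()]
    lo = min(e[0] for ex in transcripts.values() for e in ex)
    hi = max(e[1] for ex in transcripts.values() for e in ex)
    return annot.GeneModel(gene_id=gene_id, symbol=gene_id.lower(), chrom=chrom,
                           strand=strand, span=(lo, hi), biotype="protein_coding",
                           tss_set=tss, transcripts=transcripts)


def sj_row(chrom, start, end, strand_code, unique):
    return (chrom, start, end, strand_code, 0, 1, unique, 0, 30)


# ---------------------------------------------------------------------------
# promoter counting

def test_shared_tss_transcripts_form_one_promoter(tmp_path):
    g = gene("G1", "+", {
        "T1": [(100, 200), (300, 400)],
        "T2": [(100, 200), (500, 600)],
    })
    # both transcripts start at TSS 101; first introns differ: [201,300] & [201,500]
    sj = write_lines(tmp_path / "s1.tab", [sj_row("chr1", 201, 300, 1, 30),
                                           sj_row("chr1", 201, 500, 1, 12)])
    counts, log = ligand.junctions_to_promoter_counts([sj], [g], ["s1"])
    assert len(counts) == 1
    assert counts.loc[0, "s1"] == 42  # distinct first introns are summed
    assert log["unmatched_unique_reads"]["s1"] == 0


def test_single_exon_transcript_yields_no_promoter(tmp_path):
    g = gene("G1", "+", {"T1": [(100, 400)]})
    sj = write_lines(tmp_path / "s1.tab", [sj_row("chr1", 201, 300, 1, 10)])
    counts, log = ligand.junctions_to_promoter_counts([sj], [g], ["s1"])
    assert counts.empty
    assert log["unmatched_unique_reads"]["s1"] == 10


def test_distinct_tss_make_distinct_promoters_and_conservation(tmp_path):
    g = gene("G1", "+", {
        "T1": [(100, 200), (700, 800)],
        "T2": [(400, 500), (700, 800)],
    })
    sj = write_lines(tmp_path / "s1.tab", [sj_row("chr1", 201, 700, 1, 20),
                                           sj_row("chr1", 501, 700, 1, 7),
                                           sj_row("chr1", 901, 950, 1, 5)])
    counts, log = ligand.junctions_to_promoter_counts([sj], [g], ["s1"])
    assert len(counts) == 2
    assert sorted(counts["s1"]) == [7, 20]
    # reads in = reads counted + unmatched
    assert counts["s1"].sum() + log["unmatched_unique_reads"]["s1"] == 32


def test_internal_promoter_flagged_and_excluded(tmp_path):
    g = gene("G1", "+", {
        "T1": [(100, 200), (300, 600), (700, 800)],
        "T2": [(350, 450), (700, 800)],   # first exon inside T1's internal exon
    })
    sj = write_lines(tmp_path / "s1.tab", [sj_row("chr1", 201, 300, 1, 9),
                                           sj_row("chr1", 451, 700, 1, 4)])
    counts, log = ligand.junctions_to_promoter_counts([sj], [g], ["s1"])
    assert log["n_internal_promoters"] == 1
    assert counts["tss_position"].tolist() == [101]
    kept_all, _ = ligand.junctions_to_promoter_counts([sj], [g], ["s1"],
                                                      drop_internal=False)
    assert kept_all["internal"].tolist() == [False, True]


def test_minus_strand_first_intron(tmp_path):
    g = gene("G1", "-", {"T1": [(100, 200), (300, 400)]})
    # 5'-most exon on minus strand is [300,400); first intron is [201, 300]
    sj = write_lines(tmp_path / "s1.tab", [sj_row("chr1", 201, 300, 2, 11)])
    counts, _ = ligand.junctions_to_promoter_counts([sj], [g], ["s1"])
    assert counts.loc[0, "s1"] == 11
    assert counts.loc[0, "tss_position"] == 400


def test_bad_strand_code_rejected(tmp_path):
    sj = write_lines(tmp_path / "bad.tab", [sj_row("chr1", 201, 300, 7, 1)])
    g = gene("G1", "+", {"T1": [(100, 200), (300, 400)]})
    with pytest.raises(Exception, match="strand code"):
        ligand.junctions_to_promoter_counts([sj], [g], ["s1"])


# ---------------------------------------------------------------------------
# CPM filter

def test_cpm_filter_boundaries():
    # a single sample with a library of exactly one million reads
    df = pd.DataFrame({"promoter_id": ["a", "b", "c", "d"], "gene_id": ["g"] * 4,
                       "s1": [2, 1, 0, 10 ** 6 - 3]})
    out, lib = ligand.cpm_filter(df, ["s1"])
    ids = out["promoter_id"].tolist()
    assert "a" in ids      # CPM 2 > 1
    assert "b" not in ids  # CPM exactly 1 fails the strict inequality
    assert "c" not in ids  # all-zero row
    assert lib[0] == out["s1"].sum()  # library recomputed on retained rows


def test_relaxed_mode_superset_of_strict(default_world):
    cfg, man = default_world
    models = annot.parse_gene_models(man["files"]["gtf"])
    sample_ids = man["sample_ids"]
    counts, _ = ligand.junctions_to_promoter_counts(man["files"]["sj"], models,
                                                    sample_ids)
    counts, _ = ligand.cpm_filter(counts, sample_ids)
    strict = ligand.ligand_diff_usage(counts, sample_ids, man["groups"], "strict")
    relaxed = ligand.ligand_diff_usage(counts, sample_ids, man["groups"], "relaxed")
    s = set(strict.loc[strict["is_ap"], "promoter_id"])
    r = set(relaxed.loc[relaxed["is_ap"], "promoter_id"])
    assert s <= r
    assert len(s) > 0  # planted switches are detectable from junctions too


# ---------------------------------------------------------------------------
# nearest-G4 distances

def bed(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for col, val in (("name", "."), ("score", 0.0), ("strand", "+")):
        df[col] = val
    return df[BED_COLUMNS]


def prom(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tss_position"])
    df["promoter_id"] = [f"p{i}" for i in range(len(df))]
    return df


def test_distance_overlap_and_gap():
    hits = bed([("chr1", 1300, 1330)])
    aps = prom([("chr1", 1290, 1310, 1291), ("chr1", 1000, 1100, 1001)])
    bg = prom([("chr1", 5000, 5100, 5001)] * 4)
    out = ligand.nearest_g4_distance(aps, hits, bg, n_random=2, seed=1)
    assert out["distances_ap"].tolist() == [0.0, 200.0]


def test_distance_identical_sets_give_null_p(rng):
    hits = bed([("chr1", int(a), int(a) + 25) for a in rng.integers(0, 10 ** 6, 80)])
    pool = prom([("chr1", int(a), int(a) + 100, int(a) + 1)
                 for a in rng.integers(0, 10 ** 6, 60)])
    out = ligand.nearest_g4_distance(pool, hits, pool, n_random=60, seed=2)
    assert 0.3 < out["p_one_tailed"] < 0.7


def test_distance_translation_invariance(rng):
    hits_rows = [("chr1", int(a), int(a) + 25) for a in rng.integers(0, 10 ** 5, 40)]
    ap_rows = [("chr1", int(a), int(a) + 50, int(a) + 1)
               for a in rng.integers(0, 10 ** 5, 10)]
    bg_rows = [("chr1", int(a), int(a) + 50, int(a) + 1)
               for a in rng.integers(0, 10 ** 5, 30)]
    shift = 7_777
    out1 = ligand.nearest_g4_distance(prom(ap_rows), bed(hits_rows),
                                      prom(bg_rows), seed=3)
    out2 = ligand.nearest_g4_distance(
        prom([(c, s + shift, e + shift, t + shift) for c, s, e, t in ap_rows]),
        bed([(c, s + shift, e + shift) for c, s, e in hits_rows]),
        prom([(c, s + shift, e + shift, t + shift) for c, s, e, t in bg_rows]),
        seed=3)
    assert out1["distances_ap"].tolist() == out2["distances_ap"].tolist()
    assert out1["distances_random"].tolist() == out2["distances_random"].tolist()


def test_random_baseline_reproducible_and_seed_sensitive(rng):
    hits = bed([("chr1", int(a), int(a) + 25) for a in rng.integers(0, 10 ** 6, 50)])
    aps = prom([("chr1", 100, 200, 101)])
    bg = prom([("chr1", int(a), int(a) + 100, int(a) + 1)
               for a in rng.integers(0, 10 ** 6, 200)])
    a = ligand.nearest_g4_distance(aps, hits, bg, n_random=50, seed=5)
    b = ligand.nearest_g4_distance(aps, hits, bg, n_random=50, seed=5)
    c = ligand.nearest_g4_distance(aps, hits, bg, n_random=50, seed=6)
    assert a["distances_random"].tolist() == b["distances_random"].tolist()
    assert a["distances_random"].tolist() != c["distances_random"].tolist()
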