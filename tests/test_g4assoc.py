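"""G4-promoter association, enrichment, density, signal, and directionality."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4prom import g4assoc


def prom_frame(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# association

def test_associate_overlap_and_upstream_boundary():
    proms = prom_frame([("p1", "chr1", 1000, 1200, "+")])
    hit = {"c": peak_frame([("chr1", 950, 1010)])}
    out = g4assoc.associate_g4(proms, hit)
    assert out["assoc_c"].tolist() == [True]

    # upstream window of a + promoter is [900, 1000); a peak ending at 900
    # shares no base with it
    miss = {"c": peak_frame([("chr1", 890, 900)])}
    assert g4assoc.associate_g4(proms, miss)["assoc_c"].tolist() == [False]
    touch = {"c": peak_frame([("chr1", 890, 901)])}
    assert g4assoc.associate_g4(proms, touch)["assoc_c"].tolist() == [True]


def test_associate_minus_strand_upstream_is_rightward():
    proms = prom_frame([("p1", "chr1", 1000, 1200, "-")])
    out = g4assoc.associate_g4(proms, {"c": peak_frame([("chr1", 1250, 1260)])})
    assert out["assoc_c"].tolist() == [True]
    out = g4assoc.associate_g4(proms, {"c": peak_frame([("chr1", 900, 950)])})
    assert out["assoc_c"].tolist() == [False]


def test_associate_invariant_to_order_and_split():
    proms = prom_frame([("p1", "chr1", 1000, 1200, "+"),
                        ("p2", "chr1", 5000, 5100, "+")])
    whole = {"c": peak_frame([("chr1", 1100, 1180), ("chr1", 4000, 4100)])}
    split = {"c": peak_frame([("chr1", 4000, 4100), ("chr1", 1140, 1180),
                              ("chr1", 1100, 1140)])}
    a = g4assoc.associate_g4(proms, whole)["assoc_c"].tolist()
    b = g4assoc.associate_g4(proms, split)["assoc_c"].tolist()
    assert a == b == [True, False]


def test_categories_from_two_conditions():
    proms = prom_frame([("p1", "chr1", 100, 200, "+"),
                        ("p2", "chr1", 500, 600, "+"),
                        ("p3", "chr1", 900, 1000, "+")])
    peaks = {"k": peak_frame([("chr1", 120, 130), ("chr1", 520, 530)]),
             "h": peak_frame([("chr1", 120, 130)])}
    out = g4assoc.associate_g4(proms, peaks)
    assert out["category"].tolist() == ["both", "one", "neither"]


# ---------------------------------------------------------------------------
# Fisher exact 2 x c

def enumeration_oracle_2xc(table):
    """Sum multivariate hypergeometric probabilities over every table with the
    observed margins whose probability is <= the observed one (brute force via
    itertools, independent of the implementation's recursion)."""
    table = np.asarray(table)
    col = table.sum(axis=0)
    r1 = table[0].sum()
    n = table.sum()

    def prob(row):
        num = 1.0
        for c, a in zip(col, row):
            num *= comb(int(c), int(a))
        return num / comb(int(n), int(r1))

    p_obs = prob(table[0])
    total = 0.0
    for row in itertools.product(*(range(int(c) + 1) for c in col)):
        if sum(row) != r1:
            continue
        pr = prob(row)
        if pr <= p_obs * (1 + 1e-9):
            total += pr
    return total


def test_fisher_2x2_matches_scipy():
    table = np.array([[8, 2], [1, 5]])
    ours = g4assoc.fisher_exact_2xc(table)
    ref = stats.fisher_exact(table, alternative="two-sided").pvalue
    assert ours == pytest.approx(ref, rel=1e-9)


@pytest.mark.parametrize("seed", range(30))
def test_fisher_2x3_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    table = rng.integers(0, 7, size=(2, 3))
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        table = table + 1
    assert g4assoc.fisher_exact_2xc(table) == \
        pytest.approx(enumeration_oracle_2xc(table), rel=1e-9)


def test_fisher_monte_carlo_agrees_with_exact():
    table = np.array([[20, 10, 5], [15, 25, 30]])
    exact = g4assoc.fisher_exact_2xc(table)
    mc = g4assoc.fisher_exact_2xc(table, max_exact_tables=1, n_mc=200_000, seed=4)
    assert mc == pytest.approx(exact, abs=0.01)


def test_enrichment_identical_distributions():
    rec = pd.DataFrame({"category": ["neither"] * 40 + ["one"] * 40 + ["both"] * 40})
    ap = np.zeros(120, dtype=bool)
    ap[0:10] = ap[40:50] = ap[80:90] = True  # same composition as background
    out = g4assoc.category_enrichment(rec, ap)
    assert out["fisher_p"] == pytest.approx(1.0)
    for cat in g4assoc.CATEGORIES:
        assert out["ratios"][cat] == pytest.approx(1.0)


def test_enrichment_extreme_separation_on_toy():
    # all APs "neither", all others "both": p should match the brute oracle
    rec = pd.DataFrame({"category": ["neither"] * 6 + ["both"] * 14})
    ap = np.array([True] * 6 + [False] * 14)
    out = g4assoc.category_enrichment(rec, ap)
    table = np.array([[6, 0, 0], [0, 0, 14]])
    assert out["fisher_p"] == pytest.approx(enumeration_oracle_2xc(table), rel=1e-9)
    assert out["ratios"]["neither"] > 1


# ---------------------------------------------------------------------------
# relative density

def g4_cover_everything():
    return peak_frame([("chr1", 0, 100_000)])


def test_density_saturation_and_emptiness():
    proms = prom_frame([("p1", "chr1", 2000, 2500, "+"),
                        ("p2", "chr1", 8000, 8600, "-")])
    prof = g4assoc.relative_density(proms, g4_cover_everything(), flank=100)
    assert np.allclose(prof.values, 1.0)
    empty = peak_frame([("chr2", 0, 10)])
    prof = g4assoc.relative_density(proms, empty, flank=100)
    assert np.allclose(prof.values, 0.0)


def test_density_half_covered_window():
    proms = prom_frame([("p1", "chr1", 2000, 2500, "+"),
                        ("p2", "chr1", 9000, 9500, "+")])
    g4 = peak_frame([("chr1", 1000, 3000)])  # covers p1 entirely, p2 not at all
    prof = g4assoc.relative_density(proms, g4, flank=100)
    assert np.allclose(prof.values, 0.5)  # M = 2, one region covered
    assert prof.values.min() >= 0 and prof.values.max() <= 1
    # the literal printed-denominator variant scales by M / N
    assert np.allclose(prof.values_printed,
                       prof.values * prof.m_regions / prof.n_windows)


def test_density_additivity_over_disjoint_sets(rng):
    g4 = peak_frame([("chr1", int(a), int(a) + 40)
                     for a in rng.integers(0, 50_000, size=60)])
    set1 = prom_frame([("a", "chr1", 10_000, 10_400, "+"),
                       ("b", "chr1", 20_000, 20_700, "-")])
    set2 = prom_frame([("c", "chr1", 30_000, 30_500, "+")])
    both = pd.concat([set1, set2], ignore_index=True)
    p1 = g4assoc.relative_density(set1, g4, flank=200)
    p2 = g4assoc.relative_density(set2, g4, flank=200)
    pb = g4assoc.relative_density(both, g4, flank=200)
    expected = (p1.values * 2 + p2.values * 1) / 3
    assert np.allclose(pb.values, expected, atol=1e-12)


def test_density_minus_strand_orientation():
    # a G4 just 5' of a minus-strand promoter must appear in the upstream
    # (left) half of the profile
    proms = prom_frame([("p1", "chr1", 5000, 5500, "-")])
    g4 = peak_frame([("chr1", 5500, 5600)])  # genomically right = 5' upstream
    prof = g4assoc.relative_density(proms, g4, flank=200)
    nf = 200 // 10
    assert prof.values[:nf].sum() > 0
    assert np.allclose(prof.values[nf:], 0.0)


def test_density_flank_must_be_multiple_of_width():
    proms = prom_frame([("p1", "chr1", 100, 400, "+")])
    with pytest.raises(ValueError, match="multiple"):
        g4assoc.relative_density(proms, g4_cover_everything(), flank=105)


# ---------------------------------------------------------------------------
# signal

def test_signal_constant_track(tmp_path):
    from g4prom.io import read_signal
    bg = tmp_path / "t.bedgraph"
    bg.write_text("chr1\t0\t100000\t2.5\n")
    track = read_signal(bg)
    proms = prom_frame([("p1", "chr1", 1000, 1200, "+"),
                        ("p2", "chr1", 5000, 5600, "-")])
    out = g4assoc.signal_at_promoters(proms, {"k": track, "h": track})
    assert np.allclose(out["mean_k"], 2.5)
    assert np.allclose(out["delta_signal"], 0.0)


def test_rank_sum_enumeration_oracle():
    # {3,4} vs {1,2}: all orderings favor the first group; exact p = 1/C(4,2)
    assert g4assoc.rank_sum_one_tailed([3, 4], [1, 2]) == pytest.approx(1 / 6)
    x = np.arange(20.0)
    assert 0.4 < g4assoc.rank_sum_one_tailed(x, x + 0.0) < 0.6


# ---------------------------------------------------------------------------
# directionality

def ap_row(gene, direction, g4_a, g4_b):
    return {"gene_id": gene, "direction": direction,
            "assoc_condA": g4_a, "assoc_condB": g4_b}


def classify(rows):
    calls = g4assoc.classify_directionality(pd.DataFrame(rows),
                                            cond_names=("condA", "condB"))
    return {c.gene_id: c.pattern for c in calls}


def test_directionality_patterns():
    # one AP up in condB with condB-only G4 -> the G4 promotes activity
    assert classify([ap_row("g1", "up_condB", False, True)]) == {"g1": "promotes"}
    # G4 only in the condition where the AP is weaker -> represses
    assert classify([ap_row("g2", "up_condB", True, False)]) == {"g2": "represses"}
    # APs up in both directions, each promoted by its own condition's G4
    assert classify([ap_row("g3", "up_condA", True, False),
                     ap_row("g3", "up_condB", False, True)]) == \
        {"g3": "bidirectional_promotes"}
    assert classify([ap_row("g4", "up_condA", False, True),
                     ap_row("g4", "up_condB", True, False)]) == \
        {"g4": "bidirectional_represses"}
    # promoting and repressing within one gene -> mixed
    assert classify([ap_row("g5", "up_condB", False, True),
                     ap_row("g5", "up_condB", True, False)]) == {"g5": "mixed"}
    # G4 in both conditions is neutral; no effect evidence -> mixed bucket
    assert classify([ap_row("g6", "up_condB", True, True)]) == {"g6": "mixed"}
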