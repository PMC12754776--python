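"""TMM, dispersion estimation, and the relative promoter-usage test."""

import numpy as np
import pandas as pd
import pytest

from g4prom import diffusage
from g4prom.synth import SynthConfig, simulate_usage_counts


# ---------------------------------------------------------------------------
# TMM

def test_tmm_identical_columns_are_unit():
    c = np.tile(np.arange(1, 101)[:, None], (1, 4))
    assert np.allclose(diffusage.tmm_factors(c), 1.0)


def test_tmm_depth_difference_is_absorbed_by_library_size():
    # a column that is an exact multiple of another differs only in depth;
    # TMM corrects composition, not depth, so factors stay at 1
    rng = np.random.default_rng(5)
    base = rng.poisson(80, size=300)
    c = np.c_[base, base * 2]
    assert np.allclose(diffusage.tmm_factors(c), 1.0)


def test_tmm_geometric_mean_one():
    rng = np.random.default_rng(7)
    c = rng.poisson(rng.gamma(2, 20, size=(500, 1)), size=(500, 6))
    f = diffusage.tmm_factors(c)
    assert np.prod(f) == pytest.approx(1.0)


def test_tmm_composition_bias_detected():
    # a minority of rows 4x up in sample 2 inflate its library; after trimming
    # them away, TMM shrinks that sample's factor so the unchanged majority of
    # rows regain equal normalized abundance
    rng = np.random.default_rng(9)
    base = rng.poisson(100, size=(400, 2))
    biased = base.copy()
    biased[:100, 1] *= 4
    f = diffusage.tmm_factors(biased)
    assert f[1] < 0.9 < 1.1 < f[0]


# ---------------------------------------------------------------------------
# dispersion

def test_dispersion_poisson_limit(rng):
    counts = rng.poisson(100, size=(800, 12))
    groups = ["a"] * 6 + ["b"] * 6
    phi = diffusage.estimate_dispersion(counts, groups, counts.sum(axis=0) * 1.0)
    assert phi < 0.005


def test_dispersion_recovers_simulated_value(rng):
    mean = rng.gamma(3, 40, size=(500, 1))
    lam = rng.gamma(1 / 0.1, mean * 0.1)
    counts = rng.poisson(np.broadcast_to(lam, (500, 1)) * np.ones(12))
    lam12 = rng.gamma(1 / 0.1, np.broadcast_to(mean * 0.1, (500, 12)))
    counts = rng.poisson(lam12)
    groups = ["a"] * 6 + ["b"] * 6
    phi = diffusage.estimate_dispersion(counts, groups)
    assert 0.05 <= phi <= 0.2


def test_dispersion_constant_counts_zero():
    counts = np.full((50, 8), 30)
    phi = diffusage.estimate_dispersion(counts, ["a"] * 4 + ["b"] * 4,
                                        np.full(8, 1500.0))
    assert phi == 0.0


# ---------------------------------------------------------------------------
# BH

def test_bh_hand_examples():
    assert np.allclose(diffusage.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(diffusage.bh_fdr([1.0, 1.0]), [1.0, 1.0])
    assert diffusage.bh_fdr([0.2])[0] == pytest.approx(0.2)
    q = diffusage.bh_fdr([0.01, np.nan, 0.04])
    assert np.isnan(q[1]) and q[0] == pytest.approx(0.02)


# ---------------------------------------------------------------------------
# usage test

def two_promoter_counts(rng, n_genes, depth, phi, share_a, share_b, n=6):
    """Counts for genes with two promoters at the given usage shares."""
    shares = np.array([[share_a, share_b], [1 - share_a, 1 - share_b]])
    gene_ids = np.repeat([f"g{i}" for i in range(n_genes)], 2)
    prom_ids = np.array([f"g{i}:p{j}" for i in range(n_genes) for j in (1, 2)])
    expr = rng.lognormal(0, 0.4, size=n_genes)
    means = np.empty((2 * n_genes, 2 * n))
    which = np.arange(2 * n_genes) % 2  # promoter 1 or 2 within the gene
    for j in range(2 * n):
        cond = 0 if j < n else 1
        means[:, j] = depth * np.repeat(expr, 2) * shares[which, cond]
    lam = rng.gamma(1 / phi, means * phi)
    counts = rng.poisson(lam)
    groups = ["condA"] * n + ["condB"] * n
    return counts, prom_ids, gene_ids, groups


def test_gene_level_change_is_not_usage_change(rng):
    # proportions identical across conditions, all counts doubled in condB:
    # relative logFC should hover near zero and p should not be extreme
    counts, prom, gene, groups = two_promoter_counts(rng, 100, 150, 0.05, 0.7, 0.7)
    counts[:, 6:] *= 2
    res = diffusage.diff_usage_test(counts, prom, gene, groups)
    assert np.nanmedian(np.abs(res["rel_logfc"])) < 0.25
    assert np.nanmedian(res["p"]) > 0.3


def test_power_on_planted_four_fold_switch(rng):
    # promoter 1 at 80% -> 20% of gene output, 6+6 samples, depth 200
    counts, prom, gene, groups = two_promoter_counts(rng, 200, 200, 0.05, 0.8, 0.2)
    res = diffusage.diff_usage_test(counts, prom, gene, groups)
    res = diffusage.call_aps(res)
    p1 = res[res["promoter_id"].str.endswith(":p1")]
    assert p1["is_ap"].mean() >= 0.9
    # promoter 1 falls in condB: direction must reflect the contrast
    assert (p1.loc[p1["is_ap"], "direction"] == "up_condA").mean() == 1.0


def test_single_promoter_gene_gets_no_p(rng):
    counts = rng.poisson(100, size=(3, 8))
    res = diffusage.diff_usage_test(counts, ["a:p1", "b:p1", "b:p2"],
                                    ["a", "b", "b"], ["x"] * 4 + ["y"] * 4)
    assert np.isnan(res.loc[res["gene_id"] == "a", "p"]).all()
    assert res.loc[res["gene_id"] == "b", "p"].notna().all()


def test_call_aps_thresholds():
    res = pd.DataFrame({
        "promoter_id": list("abcd"), "gene_id": list("wxyz"),
        "logfc_condition": [1.2, 0.9, 1.2, 3.0],
        "rel_logfc": [1.2, 0.9, 1.2, 3.0],
        "fdr": [0.04, 0.04, 0.05, np.nan],
        "p": [0.001, 0.001, 0.001, np.nan],
    })
    out = diffusage.call_aps(res)
    assert out["is_ap"].tolist() == [True, False, False, False]
    # 2^1.2 = 2.30 > 2 -> AP; 2^0.9 = 1.87 -> not; fdr == 0.05 exactly -> not


# ---------------------------------------------------------------------------
# invariants

def test_depth_scaling_invariance_of_rel_logfc(rng):
    # under Poisson weighting (phi = 0) the pooled-rate fit is exactly
    # invariant to a uniform depth rescaling absorbed by the offsets
    # (no stabilizing prior: the pseudocount's influence legitimately shrinks
    # with depth, which would otherwise mask the exact identity)
    counts, prom, gene, groups = two_promoter_counts(rng, 60, 150, 0.05, 0.6, 0.3)
    res1 = diffusage.diff_usage_test(counts, prom, gene, groups, phi=0.0,
                                     prior_count=0.0)
    res2 = diffusage.diff_usage_test(counts * 3, prom, gene, groups, phi=0.0,
                                     prior_count=0.0)
    assert np.allclose(res1["rel_logfc"], res2["rel_logfc"], atol=1e-9)
    # scaling a single sample changes the NB mean-variance weighting, so the
    # fit is only approximately invariant there
    scaled = counts.copy().astype(float)
    scaled[:, 0] *= 3
    res3 = diffusage.diff_usage_test(scaled, prom, gene, groups, phi=0.05)
    res4 = diffusage.diff_usage_test(counts, prom, gene, groups, phi=0.05)
    assert np.allclose(res3["rel_logfc"], res4["rel_logfc"], atol=0.05)


def test_label_swap_antisymmetry(rng):
    counts, prom, gene, groups = two_promoter_counts(rng, 60, 150, 0.05, 0.6, 0.3)
    res1 = diffusage.diff_usage_test(counts, prom, gene, groups, phi=0.05)
    swapped = ["condB" if g == "condA" else "condA" for g in groups]
    res2 = diffusage.diff_usage_test(counts, prom, gene, swapped, phi=0.05)
    assert np.allclose(res1["rel_logfc"], -res2["rel_logfc"], atol=1e-8)


def test_within_gene_weighted_balance(rng):
    counts, prom, gene, groups = two_promoter_counts(rng, 60, 150, 0.05, 0.6, 0.3)
    res = diffusage.diff_usage_test(counts, prom, gene, groups)
    for _, sub in res.dropna(subset=["rel_logfc"]).groupby("gene_id"):
        w = 1.0 / sub["var_logfc"].to_numpy()
        assert abs(np.sum(w * sub["rel_logfc"].to_numpy())) < 1e-8 * np.sum(w)


def test_null_calibration_type_one_error():
    cfg = SynthConfig(seed=77, n_genes=800, single_promoter_prob=0.0,
                      switch_fraction=0.0)
    counts, truth, groups = simulate_usage_counts(cfg)
    res = diffusage.diff_usage_test(counts, truth["promoter_id"],
                                    truth["gene_id"], groups)
    p = res["p"].dropna()
    assert len(p) >= 2000
    assert 0.03 <= (p < 0.05).mean() <= 0.07
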