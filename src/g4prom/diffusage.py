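"""Differential promoter usage between two conditions.

The test asks whether a promoter's share of its gene's output changes
between conditions, not whether the gene's expression changes.  Promoter
counts are TMM-normalized, a common negative-binomial dispersion phi is
estimated, each promoter's condition log-fold-change (logFC) is fit by a
per-group NB maximum-likelihood with log(effective library size) offsets,
and the promoter logFC is contrasted against the inverse-variance-weighted
mean logFC of its gene's promoters (a diffSplice-style statistic).  The
squared standardized relative logFC is referenced to an F(1, df) with
pooled residual df; genes with a single expressed promoter are excluded
from testing.  Alternative promoters (APs) are promoters with
Benjamini-Hochberg FDR < 0.05 and |relative fold change| > 2 by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LN2 = np.log(2.0)
DEFAULT_ALPHA = 0.05
DEFAULT_FC_MIN = 2.0
DEFAULT_PRIOR_COUNT = 0.125


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(counts: np.ndarray, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean across samples.  For each sample, M (log2 ratio of
    library-normalized counts vs the reference) and A (average log2
    abundance) are computed over rows positive in both; the upper and lower
    `logratio_trim` tails of M and `sum_trim` tails of A are discarded and
    the factor is 2 to the precision-weighted mean of the surviving M.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a promoters x samples matrix with >= 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("all-zero sample")
    if np.count_nonzero(counts.any(axis=1)) < 2:
        # degenerate: a single informative row cannot anchor relative scaling
        import warnings
        warnings.warn("degenerate count matrix; returning unit TMM factors")
        return np.ones(counts.shape[1])
    frac = counts / lib
    uq = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        y, n = counts[:, j], lib[j]
        ok = (y > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        m = np.log2((y[ok] / n) / (yr[ok] / nr))
        a = 0.5 * np.log2((y[ok] / n) * (yr[ok] / nr))
        w = (n - y[ok]) / (n * y[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        keep = np.ones(ok.sum(), dtype=bool)
        for vec, trim in ((m, logratio_trim), (a, sum_trim)):
            lo, hi = np.quantile(vec, [trim, 1 - trim])
            keep &= (vec >= lo) & (vec <= hi)
        if keep.sum() == 0 or np.sum(1.0 / w[keep]) == 0:
            continue
        factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def effective_lib_sizes(counts: np.ndarray, factors: np.ndarray | None = None) -> np.ndarray:
    lib = np.asarray(counts, dtype=float).sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    return lib * factors


# ---------------------------------------------------------------------------
# NB fitting

def _group_masks(groups) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    # contrast: second level (sorted) vs first, so swapping labels negates it
    return groups == levels[0], groups == levels[1], (str(levels[0]), str(levels[1]))


def _fit_rates(y: np.ndarray, eff_lib: np.ndarray, phi: float,
               n_iter: int = 50, tol: float = 1e-12) -> np.ndarray:
    """Per-row NB MLE of the rate q with means mu_j = N_j * q (Newton on log q).

    Solves sum_j (y_j - mu_j) / (1 + phi * mu_j) = 0; reduces to the Poisson
    rate sum(y)/sum(N) at phi = 0.  Rows with sum(y) = 0 get q = 0.
    """
    tot = y.sum(axis=1)
    q0 = tot / eff_lib.sum()
    if phi == 0:
        return q0
    pos = tot > 0
    logq = np.log(np.where(pos, q0, 1.0))
    for _ in range(n_iter):
        mu = eff_lib * np.exp(logq)[:, None]
        denom = 1.0 + phi * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(mu * (1.0 + phi * y) / denom ** 2).sum(axis=1)
        step = np.where(pos & (fp != 0), f / fp, 0.0)
        step = np.clip(step, -5, 5)
        logq = logq - step
        if np.max(np.abs(step)) < tol:
            break
    return np.where(pos, np.exp(logq), 0.0)


def fit_condition_logfc(counts: np.ndarray, groups, eff_lib: np.ndarray,
                        phi: float, prior_count: float = DEFAULT_PRIOR_COUNT
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-promoter condition logFC (log2, second vs first level) and its variance.

    A small library-size-proportional prior count stabilizes logFCs of
    promoters with empty groups.  Variances come from the expected Fisher
    information of the per-group fits.
    """
    counts = np.asarray(counts, dtype=float)
    mask_a, mask_b, _ = _group_masks(groups)
    prior = prior_count * eff_lib / eff_lib.mean()
    aug = counts + prior
    out = []
    for mask in (mask_a, mask_b):
        q = _fit_rates(aug[:, mask], eff_lib[mask], phi)
        mu = eff_lib[mask] * q[:, None]
        info = (mu / (1.0 + phi * mu)).sum(axis=1)
        out.append((np.log(q), 1.0 / info))
    (logq_a, var_a), (logq_b, var_b) = out
    logfc = (logq_b - logq_a) / LN2
    var = (var_a + var_b) / LN2 ** 2
    return logfc, var


def estimate_dispersion(counts: np.ndarray, groups, eff_lib: np.ndarray | None = None,
                        phi_max: float = 5.0, tol: float = 1e-6) -> float:
    """Common NB dispersion by matching the pooled Pearson statistic to its df.

    A method-of-moments (pseudo-likelihood) estimate: find phi >= 0 such that
    sum (y - mu)^2 / (mu (1 + phi mu)), with group means refit at each phi,
    equals the pooled residual degrees of freedom.  Returns 0 when the data
    are under-dispersed relative to Poisson.
    """
    counts = np.asarray(counts, dtype=float)
    mask_a, mask_b, _ = _group_masks(groups)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need >= 2 samples per condition to estimate dispersion")
    if eff_lib is None:
        eff_lib = effective_lib_sizes(counts)

    def pearson_excess(phi: float) -> float:
        x2, df = 0.0, 0
        for mask in (mask_a, mask_b):
            q = _fit_rates(counts[:, mask], eff_lib[mask], phi)
            mu = eff_lib[mask] * q[:, None]
            ok = mu > 0
            x2 += float(((counts[:, mask] - mu) ** 2 / (mu * (1 + phi * mu)))[ok].sum())
            df += int(ok.sum() - (q > 0).sum())
        return x2 - df

    if pearson_excess(0.0) <= 0:
        return 0.0
    lo, hi = 0.0, phi_max
    if pearson_excess(hi) > 0:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pearson_excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# diffSplice-style usage test

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are ignored and returned as NaN."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if (np.nanmin(p, initial=0) < 0) or (np.nanmax(p, initial=0) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def diff_usage_test(counts: np.ndarray, promoter_ids, gene_ids, groups,
                    norm_factors: np.ndarray | None = None,
                    phi: float | None = None,
                    prior_count: float = DEFAULT_PRIOR_COUNT) -> pd.DataFrame:
    """Relative promoter-usage test for every promoter of multi-promoter genes.

    Returns one row per promoter with the condition logFC, the relative logFC
    (promoter minus inverse-variance-weighted gene average), the F statistic,
    p, and BH FDR.  Single-promoter genes appear with NaN statistics and do
    not enter the FDR correction; all-zero promoters are dropped.
    """
    counts = np.asarray(counts, dtype=float)
    promoter_ids = np.asarray(promoter_ids)
    gene_ids = np.asarray(gene_ids)
    mask_a, mask_b, levels = _group_masks(groups)

    nonzero = counts.sum(axis=1) > 0
    counts, promoter_ids, gene_ids = counts[nonzero], promoter_ids[nonzero], gene_ids[nonzero]
    n_dropped_zero = int((~nonzero).sum())

    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * norm_factors
    if phi is None:
        phi = estimate_dispersion(counts, groups, eff_lib)

    logfc, var = fit_condition_logfc(counts, groups, eff_lib, phi, prior_count)

    res = pd.DataFrame({
        "promoter_id": promoter_ids, "gene_id": gene_ids,
        "logfc_condition": logfc, "var_logfc": var,
    })
    sizes = res.groupby("gene_id")["promoter_id"].transform("size")
    res["n_promoters_gene"] = sizes

    rel = np.full(len(res), np.nan)
    var_rel = np.full(len(res), np.nan)
    testable = sizes.to_numpy() >= 2
    for _, idx in res[testable].groupby("gene_id").groups.items():
        ix = np.asarray(idx)
        w = 1.0 / var[ix]
        gene_lfc = np.sum(w * logfc[ix]) / np.sum(w)
        rel[ix] = logfc[ix] - gene_lfc
        var_rel[ix] = np.maximum(var[ix] - 1.0 / np.sum(w), 1e-12)
    res["rel_logfc"] = rel
    res["var_rel"] = var_rel

    df_resid = int(testable.sum()) * (counts.shape[1] - 2)
    stat = np.where(testable, rel ** 2 / var_rel, np.nan)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(stat, 1, max(df_resid, 1))
    res["stat"] = stat
    res["p"] = np.where(testable, p, np.nan)
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    res.attrs["phi"] = float(phi)
    res.attrs["condition_levels"] = levels
    res.attrs["n_dropped_all_zero"] = n_dropped_zero
    return res


def call_aps(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
             fc_min: float = DEFAULT_FC_MIN, on: str = "usage",
             use_fdr: bool = True) -> pd.DataFrame:
    """Flag alternative promoters: FDR < alpha (strict) and |fold change| > fc_min.

    `on="usage"` thresholds the relative (usage-level) logFC, the default;
    `on="condition"` thresholds the promoter-level condition logFC instead.
    With `use_fdr=False` the unadjusted p-value is thresholded (the relaxed
    mode used for weak ligand responses).
    """
    if on not in ("usage", "condition"):
        raise ValueError("on must be 'usage' or 'condition'")
    lfc = results["rel_logfc"] if on == "usage" else results["logfc_condition"]
    crit = results["fdr"] if use_fdr else results["p"]
    out = results.copy()
    out["is_ap"] = (crit < alpha) & (np.abs(lfc) > np.log2(fc_min)) & crit.notna()
    cond_a, cond_b = out.attrs.get("condition_levels", ("condA", "condB"))
    out["direction"] = np.where(lfc > 0, f"up_{cond_b}", f"up_{cond_a}")
    out.loc[~out["is_ap"], "direction"] = ""
    out.attrs.update(results.attrs)
    return out
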