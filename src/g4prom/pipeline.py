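"""End-to-end orchestration: CTSS -> tag clusters -> annotated promoters ->
differential usage -> G4 association statistics, with a run manifest.

The manifest records, for every filtering stage, the records in, the records
out, and the records dropped itemized by reason, so that counts are conserved
across the whole run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annot, diffusage, g4assoc, tssclust
from . import io as g4io

DEFAULT_PARAMS = {
    "window": 25, "threshold": 1.5,
    "merge_dist": 20, "min_tpm": 1.0, "min_support_samples": 6,
    "min_fraction": 0.10, "min_composition_samples": 6,
    "upstream_assign": 1000, "upstream_g4": 100,
    "alpha": 0.05, "fc_min": 2.0,
}


class RunManifest:
    """Stage-by-stage record accounting: in = out + sum(dropped by reason)."""

    def __init__(self, params: dict):
        self.params = dict(params)
        self.stages: list[dict] = []

    def record(self, stage: str, n_in: int, n_out: int, dropped: dict[str, int]):
        if n_in != n_out + sum(dropped.values()):
            raise ValueError(f"stage {stage}: {n_in} in != {n_out} out "
                             f"+ {sum(dropped.values())} dropped")
        self.stages.append({"stage": stage, "in": int(n_in), "out": int(n_out),
                            "dropped": {k: int(v) for k, v in dropped.items()}})

    def to_dict(self) -> dict:
        return {"parameters": self.params, "stages": self.stages}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def promoter_pipeline(ctss_paths: list, sample_ids: list[str], groups,
                      gtf_path, peaks: dict[str, pd.DataFrame] | None = None,
                      signal_tracks: dict | None = None,
                      exclusion_bed=None, params: dict | None = None,
                      enrichment_seed: int = 0) -> dict:
    """Run the promoter-calling and usage-testing pipeline on CTSS inputs.

    Returns a dict with the cluster table, usage results, AP calls, and (when
    peaks are given) association records, enrichment statistics, and
    directionality calls, plus the run manifest.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    manifest = RunManifest(p)

    m = tssclust.read_ctss(ctss_paths, sample_ids)
    tcs = tssclust.call_tag_clusters(m, merge_dist=p["merge_dist"])
    manifest.record("ctss_positions", len(m.positions), len(m.positions), {})

    n0 = len(tcs)
    tcs = tssclust.support_filter(tcs, p["min_tpm"], p["min_support_samples"])
    manifest.record("support_filter", n0, len(tcs), {"low_support": n0 - len(tcs)})

    models = annot.parse_gene_models(gtf_path)
    n0 = len(tcs)
    tcs = annot.tss_overlap_filter(tcs, models, exclusion_bed)
    manifest.record("tss_overlap_filter", n0, len(tcs),
                    {"no_tss_overlap_or_excluded": n0 - len(tcs)})
    n0 = len(tcs)
    tcs = annot.assign_genes(tcs, models, upstream=p["upstream_assign"])
    manifest.record("gene_assignment", n0, len(tcs), {"unassignable": n0 - len(tcs)})
    n0 = len(tcs)
    tcs = annot.composition_filter(tcs, p["min_fraction"], p["min_composition_samples"])
    manifest.record("composition_filter", n0, len(tcs),
                    {"low_composition": n0 - len(tcs)})

    tc_frame = tssclust.clusters_to_frame(tcs, sample_ids)
    counts = np.array([tc.counts_per_sample for tc in tcs])
    results = diffusage.diff_usage_test(
        counts, [tc.id for tc in tcs], [tc.gene_id for tc in tcs], groups)
    results = diffusage.call_aps(results, alpha=p["alpha"], fc_min=p["fc_min"])
    n_tested = int(results["p"].notna().sum())
    manifest.record("usage_test", len(tcs), n_tested,
                    {"single_promoter_gene": len(tcs) - n_tested
                     - results.attrs["n_dropped_all_zero"],
                     "all_zero": results.attrs["n_dropped_all_zero"]})

    out = {"clusters": tc_frame, "results": results, "manifest": manifest,
           "models": models}
    if peaks is not None:
        tc_bed = tc_frame.rename(columns={"id": "id"})
        assoc = g4assoc.associate_g4(tc_bed, peaks, upstream=p["upstream_g4"])
        assoc = assoc.merge(results[["promoter_id", "is_ap", "direction", "rel_logfc"]],
                            left_on="id", right_on="promoter_id", how="left")
        assoc["is_ap"] = assoc["is_ap"].fillna(False).astype(bool)
        out["association"] = assoc
        out["enrichment"] = g4assoc.category_enrichment(
            assoc, assoc["is_ap"].to_numpy(), seed=enrichment_seed)
        conds = tuple(peaks)
        ap_sub = assoc[assoc["is_ap"] & assoc["gene_id"].notna()]
        if len(conds) == 2 and len(ap_sub):
            out["directionality"] = g4assoc.classify_directionality(ap_sub,
                                                                    cond_names=conds)
        if signal_tracks:
            out["signal"] = g4assoc.signal_at_promoters(tc_bed, signal_tracks)
    return out
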