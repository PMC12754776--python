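"""Generate the synthetic study world: a genome with multi-promoter genes,
NET-CAGE-style CTSS tracks for 6+6 replicates of two conditions, G4 peaks
coupled to planted promoter switches, signal tracks, and junction tables.

Writes a short summary of the planted truth to results/.
"""

import pandas as pd

from common import RESULTS, get_world


def main() -> None:
    cfg, man = get_world()
    truth = man["truth"]
    summary = {
        "n_genes": cfg.n_genes,
        "n_promoters": len(truth),
        "single_promoter_genes": int(
            (truth.groupby("gene_id")["promoter_rank"].max() == 1).sum()),
        "planted_aps": int(truth["is_planted_ap"].sum()),
        "promoters_with_g4_peak": int((truth["g4_condA"] | truth["g4_condB"]).sum()),
        "samples_per_condition": cfg.n_samples,
        "mean_depth": cfg.depth,
        "nb_dispersion": cfg.nb_dispersion,
    }
    pd.Series(summary).to_csv(RESULTS / "world_summary.tsv", sep="\t", header=False)
    print("Synthetic world written to scratch/ with the following truth:")
    for k, v in summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
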