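"""Call promoters from the CTSS tracks: tag clustering (20 bp merge),
support filter (> 1 TPM in >= 6 of 12 samples), TSS-overlap and gene
assignment against the GTF, and the > 10% composition filter.

Writes the annotated promoter table and the filter accounting to results/.
"""

import json

from common import RESULTS, get_world

from g4prom import pipeline


def main() -> None:
    cfg, man = get_world()
    res = pipeline.promoter_pipeline(
        man["files"]["ctss"], man["sample_ids"], man["groups"],
        man["files"]["gtf"])
    res["clusters"].to_csv(RESULTS / "promoters.tsv", sep="\t", index=False)
    res["manifest"].write(RESULTS / "promoter_manifest.json")
    print("Filter accounting (records in -> out):")
    for stage in res["manifest"].stages:
        drops = ", ".join(f"{k}={v}" for k, v in stage["dropped"].items()) or "none"
        print(f"  {stage['stage']}: {stage['in']} -> {stage['out']} (dropped: {drops})")
    print(f"annotated promoter table -> {RESULTS / 'promoters.tsv'}")


if __name__ == "__main__":
    main()
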