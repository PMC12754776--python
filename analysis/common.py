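"""Shared plumbing for the analysis drivers: one deterministic synthetic
world (seed 11, default configuration) under scratch/, regenerated on demand,
plus the results/ output directory."""

from pathlib import Path

from g4prom import synth

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
WORLD_SEED = 11


def get_world():
    """Simulate (or reuse) the default synthetic world and return (cfg, manifest)."""
    cfg = synth.SynthConfig(seed=WORLD_SEED)
    out = SCRATCH / f"world_seed{WORLD_SEED}"
    manifest = synth.simulate_world(cfg, out)
    RESULTS.mkdir(exist_ok=True)
    return cfg, manifest
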