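import numpy as np
import pytest

from g4prom import io as g4io
from g4prom import pipeline, synth


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    """One default-configuration synthetic world shared across tests."""
    cfg = synth.SynthConfig(seed=11)
    out = tmp_path_factory.mktemp("world")
    manifest = synth.simulate_world(cfg, out)
    return cfg, manifest


@pytest.fixture(scope="session")
def default_pipeline_run(default_world):
    cfg, man = default_world
    peaks = {c: g4io.read_bed(man["files"][f"peaks_{c}"]) for c in cfg.conditions}
    tracks = {c: g4io.read_signal(man["files"][f"signal_{c}"]) for c in cfg.conditions}
    return pipeline.promoter_pipeline(
        man["files"]["ctss"], man["sample_ids"], man["groups"],
        man["files"]["gtf"], peaks=peaks, signal_tracks=tracks)


def write_lines(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
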