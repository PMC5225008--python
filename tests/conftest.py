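import numpy as np
import pytest

import abtmap as m


SMALL_LENGTHS = {"chrA": 150_000, "chrB": 120_000, "chrC": 90_000}


@pytest.fixture(scope="session")
def small_config() -> m.SimulationConfig:
    return m.SimulationConfig(seed=7, chromosome_lengths=dict(SMALL_LENGTHS))


@pytest.fixture(scope="session")
def small_genome(small_config) -> m.Genome:
    return m.generate_reference(small_config)


@pytest.fixture(scope="session")
def translocation_result(small_genome):
    """A translocation with one microhomology junction and one insertion junction."""
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation",
        chrom_a="chrA", pos_a=80_000, chrom_b="chrB", pos_b=50_000,
        junction_ab=m.JunctionFeatures(microhomology=3),
        junction_ba=m.JunctionFeatures(insertion="GC"),
        deletion_a=3, deletion_b=0,
    )
    return spec, m.apply_rearrangement(small_genome, spec)


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    cfg = m.demo_config(tmp_path_factory.mktemp("demo"), seed=1)
    return cfg, m.run_pipeline(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
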