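import logging

import numpy as np
import pytest

from refcurate.simulate import SimulationConfig, simulate_genome

logging.getLogger("refcurate").setLevel(logging.ERROR)
logging.getLogger("refcurate.transcripts").setLevel(logging.ERROR)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast desk-scale genome used by most integration tests."""
    base = dict(seed=seed, chromosome_lengths=(120_000, 120_000),
                gene_count=12, sv_count=15, chimera_count=2,
                withheld_intervals=2, translocation_count=1,
                error_count=0, contig_n50=40_000)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def ds_small():
    """Clean (error-free) synthetic dataset shared across test modules."""
    return simulate_genome(small_config())


@pytest.fixture(scope="session")
def ds_medium():
    """A larger genome with planted consensus errors, for benchmarking."""
    return simulate_genome(SimulationConfig(
        seed=23, chromosome_lengths=(250_000, 250_000), gene_count=14,
        sv_count=25, chimera_count=3, withheld_intervals=3,
        translocation_count=1, error_count=200))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
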