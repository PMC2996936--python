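import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "tescan",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("tescan")

from tescan import (
    build_database,
    default_genome_config,
    default_library_config,
    simulate_genome,
    simulate_srna_library,
)
from tescan.srna_db import SmallRNARead


@pytest.fixture(scope="session")
def sim_genome():
    """A small annotated synthetic region shared across tests."""
    region, features, truth = simulate_genome(default_genome_config(101))
    return region, features, truth


@pytest.fixture(scope="session")
def sim_library(sim_genome):
    region, features, _ = sim_genome
    reads, truth = simulate_srna_library(
        region, features, default_library_config(202, total_reads=5_000)
    )
    return reads, truth


@pytest.fixture(scope="session")
def sim_db(sim_library):
    reads, _ = sim_library
    return build_database([reads])


def make_reads(seqs, library_id="L1"):
    return [SmallRNARead(s, library_id) for s in seqs]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
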