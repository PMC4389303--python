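import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plastomekit as pk
from plastomekit import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: a scaled-down quadripartite spec for fast structural property tests
SMALL_SPEC = pk.PlastomeSpec(lsc_len=30_000, ssc_len=6_000, ir_len=8_000,
                             n_genes=30, seed=11)

#: the four rare marker-sized events planted in recovery tests
MARKER_VARIANTS = [
    syn.VariantSpec("insertion", "rpl23-ndhB", 2706),
    syn.VariantSpec("insertion", "rps16-trnQ", 500),
    syn.VariantSpec("deletion", "petA-psbJ", 1500),
    syn.VariantSpec("inversion", "trnD-psbM", 150, flank_repeat="CCYTTTTY"),
]


@pytest.fixture(scope="session")
def plastome_full():
    """A full-size (137.5 kb) synthetic bamboo-like plastome."""
    return pk.generate_plastome(pk.PlastomeSpec(seed=7))


@pytest.fixture(scope="session")
def plastome_small():
    """A 52 kb quadripartite genome for fast structure tests."""
    return pk.generate_plastome(SMALL_SPEC)


@pytest.fixture(scope="session")
def marker_sample(plastome_full):
    """Full plastome with the four marker-like events planted."""
    sample, truth = syn.plant_variants(plastome_full, MARKER_VARIANTS, seed=42)
    return plastome_full, sample, truth


@pytest.fixture(scope="session")
def read_set(plastome_full):
    return syn.simulate_reads(plastome_full, coverage=25, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
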