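import numpy as np
import pytest

from insertion_fate.core import GenomeSpec
from insertion_fate.synth import SynthConfig, make_genome, sample_insertions


@pytest.fixture(scope="session")
def genome100():
    return GenomeSpec(100, 0, 50)


@pytest.fixture(scope="session")
def synth_config():
    # smaller world than the defaults to keep unit tests quick
    return SynthConfig(length_bp=200_000, at_island_count=10, essential_count=15,
                       n_insertions=4000, seed=11)


@pytest.fixture(scope="session")
def synth_world(synth_config):
    ann = make_genome(synth_config)
    ins = sample_insertions(ann, synth_config)
    return ann, ins


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
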