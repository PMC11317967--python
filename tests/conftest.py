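import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as plain "oracles"

from aied import io as aio
from aied.catalog import SubgroupScheme
from aied.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """60-site three-group study with known truth (fast, shared read-only)."""
    config = SimConfig(n_sites=60, seed=202, frac_dre=0.25, effect_size=0.12)
    return generate_study(config)


@pytest.fixture(scope="session")
def small_oriented(small_study):
    oriented, _ = aio.orient_to_sense(small_study.allele_counts)
    return oriented


@pytest.fixture(scope="session")
def small_scheme(small_study):
    return SubgroupScheme.from_metadata(small_study.metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(9157)
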