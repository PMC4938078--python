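import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles-style imports

from physarum_bandit import (
    DatasetSpec,
    PolicySpec,
    generate_dataset,
    make_treatment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160030)


@pytest.fixture(scope="session")
def treatment_4e_vs_8e():
    return make_treatment("4e_vs_8e", hq_side="right")


@pytest.fixture(scope="session")
def small_dataset():
    """30 relative-successes replicates over two treatments, with arenas attached."""
    spec = DatasetSpec(
        treatments=("4e_vs_8e", "4r_vs_8r"),
        n_replicates=15,
        model=PolicySpec("relative_successes", theta=0.1),
        seed=11,
    )
    trajectories, manifest = generate_dataset(spec)
    return trajectories, manifest
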