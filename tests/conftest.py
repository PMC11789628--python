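import numpy as np
import pytest

from iespipe.simulate import SimConfig, build_genome


@pytest.fixture(scope="session")
def small_pair_truth():
    """A small deterministic genome with ground truth, shared read-only."""
    cfg = SimConfig(seed=11, n_ies=20, n_scaffolds=2, scaffold_len=12000)
    pair, truth = build_genome(cfg)
    return cfg, pair, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
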