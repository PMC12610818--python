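import numpy as np
import pytest

from batmirnet import syndata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted/decoy ncRNA corpus with clean (mutation-free) arms."""
    cfg = syndata.GeneratorConfig(seed=42, n_planted=12, n_decoys=40)
    refs, hosts, truth = syndata.gen_mirna_corpus(cfg)
    return cfg, refs, hosts, truth
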