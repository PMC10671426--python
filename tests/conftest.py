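import numpy as np
import pytest

from protfit.synthetic import BlockSpec, GeneratorConfig, gen_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature study: fast enough for per-test use, same structure."""
    return GeneratorConfig(
        L=12,
        n_mutants=40,
        max_order=2,
        block_specs=(BlockSpec("emb_a", 8, 0.5), BlockSpec("emb_b", 6, 0.5)),
        coupling_sparsity=0.3,
        signal_split={"emb_a": 0.35, "emb_b": 0.35, "local": 0.30},
        noise_sd=0.1,
        seed=7,
        enforce_envelope=False,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return gen_dataset(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
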