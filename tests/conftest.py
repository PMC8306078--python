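import numpy as np
import pytest

import fruitspec as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nir_batch():
    """Default-condition NIR batch shared by read-only tests."""
    cfg = fs.GeneratorConfig(n_samples=60, region="NIR", seed=11)
    return fs.generate_batch(cfg)


@pytest.fixture(scope="session")
def noiseless_batch():
    """Noise- and baseline-free batch: the exactly linear forward model."""
    cfg = fs.GeneratorConfig(
        n_samples=40, region="NIR", noise_sd=0.0, baseline_amplitude=0.0, seed=3
    )
    return fs.generate_batch(cfg)
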