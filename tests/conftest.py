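import numpy as np
import pytest

from ordcrash import GeneratorConfig, generate


@pytest.fixture(scope="session")
def severity_dataset():
    """Mid-size synthetic 5-level severity dataset (deterministic)."""
    return generate(GeneratorConfig(N=4000, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
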