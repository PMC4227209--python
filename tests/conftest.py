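import numpy as np
import pytest

from ghstox import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A compact synthetic dataset with every planted feature present."""
    cfg = SynthConfig(
        n_chemicals=120,
        n_informative=5,
        n_noise=60,
        n_correlated_pairs=4,
        n_constant=3,
        n_near_constant=3,
        missing_rate=0.05,
        n_outliers=2,
        effect_size=2.0,
        class_target_fractions=(1 / 3, 1 / 3, 1 / 3),
        seed=42,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
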