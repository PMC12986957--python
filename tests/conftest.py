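import numpy as np
import pytest

import tidalcd as tc


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def narrow_cfg():
    """Narrow model configuration for CPU-cheap structural tests."""
    return tc.ModelConfig(base_width=16)


@pytest.fixture(scope="session")
def narrow_model(narrow_cfg):
    return tc.ChangeDetectionNet(narrow_cfg, seed=0)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Eight deterministic 64-px synthetic pairs (shared, read-only)."""
    params = tc.SceneParams(size=64, seed=11, change_rate=0.4)
    return tc.generate_split(params, 8, split_idx=0)
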