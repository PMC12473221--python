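import numpy as np
import pytest

from lmeran.config import ModelConfig
from lmeran.model import LMeRAN


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    """A small untrained model on the test backbone (d=32, 7x7 grid)."""
    cfg = ModelConfig(backbone="tiny", input_size=56,
                      labels=[f"L{i}" for i in range(6)], heads=2, layers=2)
    return LMeRAN(cfg, rng=0)


def numerical_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f at array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g
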