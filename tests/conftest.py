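import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_net():
    """A 4-channel network — full architecture, toy width."""
    from nfuse.network import FusionNet, NetConfig

    return FusionNet(NetConfig(base_channels=4), seed=7)


def finite_difference(f, x: np.ndarray, i: tuple, eps: float = 1e-6) -> float:
    """Central finite difference of scalar-valued f at x[i]."""
    xp = x.copy()
    xp[i] += eps
    xm = x.copy()
    xm[i] -= eps
    return (f(xp) - f(xm)) / (2 * eps)
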