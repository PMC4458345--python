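import numpy as np
import pytest


def digital_ball(radius: int, pad: int = 2) -> np.ndarray:
    """Boolean grid of the digital ball x²+y²+z² <= r², centered."""
    n = 2 * radius + 2 * pad + 1
    c = radius + pad
    zz, yy, xx = np.indices((n, n, n))
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def fused_pair():
    """Noiseless fused pair of radius-8 balls, centers 12 apart, with truth."""
    from los3d import generate_phantom, two_ball_spec

    return generate_phantom(two_ball_spec(8, 8, 1.5))
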