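import numpy as np
import pytest

from armik.arm_model import AnatomicalAngles, SegmentLengths


@pytest.fixture
def lengths():
    return SegmentLengths(upper_arm=0.3, forearm=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_anatomical(rng, n=1):
    """Non-degenerate anatomical configurations, uniform over safe ranges."""
    out = [
        AnatomicalAngles(
            theta=rng.uniform(0.1, np.pi - 0.1),
            eta=rng.uniform(-np.pi, np.pi),
            zeta=rng.uniform(-np.pi, np.pi),
            phi=rng.uniform(0.1, np.pi - 1e-9),
        )
        for _ in range(n)
    ]
    return out[0] if n == 1 else out
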