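import numpy as np
import pytest

from phitax import random_joint, two_bit_example


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)


@pytest.fixture
def small_joints(rng):
    """A batch of random joints of mixed subsystem sizes."""
    sizes = [(2, 2), (2, 3), (3, 2), (4, 2), (3, 3)]
    return [random_joint(nA, nB, rng) for nA, nB in sizes for _ in range(4)]


@pytest.fixture(params=["frozen_correlated", "copy_or_flip", "correlated_noise"])
def two_bit(request):
    return request.param, two_bit_example(request.param)
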