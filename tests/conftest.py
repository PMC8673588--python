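import numpy as np
import pytest

from hallumap import LinearOperator, PhantomSpec, generate, make_cartesian_mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dense_op(rng):
    """A random complex 6x16 dense operator with a known matrix."""
    matrix = rng.normal(size=(6, 16)) + 1j * rng.normal(size=(6, 16))
    return LinearOperator.from_matrix(matrix)


@pytest.fixture
def mask8():
    return make_cartesian_mask(8, 8, 3, center_offset=0)


@pytest.fixture
def phantom64():
    return generate(PhantomSpec(size=(64, 64), family="A", seed=7))


@pytest.fixture
def flat_phantom64():
    """Piecewise-constant phantom (no texture): the TV prior's favorite object."""
    return generate(PhantomSpec(size=(64, 64), family="A", seed=7, texture_amp=0.0))
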