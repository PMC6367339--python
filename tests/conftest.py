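import numpy as np
import pytest

from myonuc import SyntheticFiberSpec, generate_fiber, render_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A short, clean fibre that renders in well under a second."""
    return SyntheticFiberSpec(
        fiber_length=100.0,
        width_w=40.0,
        thickness_t=30.0,
        nuclei_per_100um=5.0,
        min_spacing=16.0,
        noise_model="none",
        seed=7,
    )


@pytest.fixture
def rendered_fiber(small_spec):
    nuclei, geometry = generate_fiber(small_spec)
    stack = render_stack(nuclei, geometry, small_spec)
    return nuclei, geometry, stack
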