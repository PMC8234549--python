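import numpy as np
import pytest

from thyromesh.phantom import Nodule, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom shared across read-only tests."""
    spec = PhantomSpec(nodules=(Nodule((0.0, 0.0, 11.0), 4.0),), seed=7)
    volume, mask, nodules = generate_phantom(spec)
    return spec, volume, mask, nodules


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
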