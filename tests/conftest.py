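import numpy as np
import pytest

from vertemetrics import phantom as ph


@pytest.fixture(scope="session")
def default_spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def phantom_1mm(default_spec):
    """Default vertebra rasterized at 1 mm: (bone, parts)."""
    return ph.rasterize_phantom(default_spec, 1.0)


@pytest.fixture(scope="session")
def phantom_half_mm(default_spec):
    """Default vertebra rasterized at 0.5 mm: (bone, parts)."""
    return ph.rasterize_phantom(default_spec, 0.5)


@pytest.fixture(scope="session")
def ball_10mm():
    return ph.ball_mask(10.0, 1.0)


@pytest.fixture(scope="session")
def spine_specs():
    rng = np.random.default_rng(42)
    return [ph.sample_spec(rng, name=n) for n in ("L5", "L4", "L3", "L2", "L1")]
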