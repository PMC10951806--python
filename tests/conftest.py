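import numpy as np
import pytest

from spatcorr import Domain, PointPattern


@pytest.fixture
def unit_km_domain() -> Domain:
    """The 1000 x 1000 μm domain used by the synthetic generators."""
    return Domain(0.0, 1000.0, 0.0, 1000.0)


@pytest.fixture
def small_domain() -> Domain:
    return Domain(0.0, 100.0, 0.0, 100.0)


def make_pattern(coords, domain, labels=None, **continuous):
    coords = np.asarray(coords, dtype=float)
    return PointPattern(coords, domain, categorical_marks=labels, continuous_marks=continuous or None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
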