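import numpy as np
import pytest

from morphoflex.geometry import GeometryConfig, build_chain


@pytest.fixture(scope="session")
def single_vesicle_mesh():
    """Default-resolution single-vesicle chain (shared, read-only)."""
    return build_chain(GeometryConfig(n_vesicles=1))


@pytest.fixture(scope="session")
def four_vesicle_mesh():
    return build_chain(GeometryConfig(n_vesicles=4))


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarse single-vesicle mesh (~150 vertices) for dense-oracle tests."""
    return build_chain(GeometryConfig(n_vesicles=1, target_edge_length=0.095))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
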