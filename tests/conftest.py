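import numpy as np
import pytest

from poolscan.models import DemographicModel, LocusSpec, fitted_constant_model


@pytest.fixture(scope="session")
def fitted_model() -> DemographicModel:
    """The constant-ancestral-size IM model at its modal estimates."""
    return fitted_constant_model()


@pytest.fixture(scope="session")
def small_loci() -> list[LocusSpec]:
    return [LocusSpec(f"g{i}", 500) for i in range(6)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
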