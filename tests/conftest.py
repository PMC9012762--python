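import numpy as np
import pytest

from bedsim import DesignConfig, PopulationConfig, ReleaseScheme


@pytest.fixture
def small_population():
    """Reduced-scale population for fast stochastic tests."""
    return PopulationConfig(carrying_capacity=5000, critical_population_size=25)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(params=["ffBED", "sBED", "ffSD"])
def design_name(request):
    return request.param


def release_for(design: str, males_per_drive: int = 250) -> ReleaseScheme:
    return ReleaseScheme(males_per_drive=males_per_drive)


def reference_design(design: str, **overrides) -> DesignConfig:
    return DesignConfig.preset(design, "RS", **overrides)
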