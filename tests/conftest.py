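import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ecocredit import SpeciesPool, build_pool  # noqa: E402


@pytest.fixture
def small_pool() -> SpeciesPool:
    """10 species, all weight 0.5."""
    return SpeciesPool(
        species_ids=tuple(f"sp{i}" for i in range(10)),
        occupancy_weights=np.full(10, 0.5),
    )


@pytest.fixture
def saturated_pool() -> SpeciesPool:
    """8 species with weight 1.0: every cell contains every species."""
    return build_pool(8, "uniform", p=1.0, seed=0)
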