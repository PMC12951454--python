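import numpy as np
import pytest

from hydrashell import AnalysisConfig, WaterPlacementSpec, make_toy_system


@pytest.fixture
def config():
    """Default cutoffs with no burn-in (toy trajectories are short)."""
    return AnalysisConfig(burn_in_time=0.0)


@pytest.fixture
def toy_pair(config):
    """Small generated system: 5 primary, 3 secondary, 2 bulk waters."""
    placements = (
        [WaterPlacementSpec("primary", 2.5) for _ in range(5)]
        + [WaterPlacementSpec("secondary", 6.0) for _ in range(3)]
        + [WaterPlacementSpec("bulk", 12.0) for _ in range(2)]
    )
    return make_toy_system(8, placements, seed=11, config=config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
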