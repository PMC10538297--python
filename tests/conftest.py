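import pytest

from ystrpop import SimulationConfig, simulate_population
from ystrpop.panels import YFILER, YPLUS44


@pytest.fixture(scope="session")
def yfiler_panel():
    return YFILER


@pytest.fixture(scope="session")
def full_panel():
    return YPLUS44


@pytest.fixture(scope="session")
def small_cohort(yfiler_panel):
    """30 simulated males on the 17-marker panel, moderate drift."""
    cfg = SimulationConfig(
        n_individuals=30, panel=yfiler_panel, generations=300, seed=11
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def study_scale_cohort(full_panel):
    """Study-scale cohort: 312 males, 44-marker panel, default mutation model."""
    cfg = SimulationConfig(seed=7)
    return simulate_population(cfg)
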