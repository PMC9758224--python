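import pytest
from hypothesis import HealthCheck, settings

from pibcm.mte import Subpopulation
from pibcm.synthetic import ScenarioSpec, gen_arrhenius_measurements

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

ACCLIMATION_TEMPS = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 33.0]


@pytest.fixture(scope="session")
def acclimation_data():
    """Noise-free acclimation rates for both subpopulations (north E=0.55,
    south E=0.65) over the full 5-33 degC assay array."""
    north = gen_arrhenius_measurements(
        0.55, 20.0, ACCLIMATION_TEMPS, 0.0, 3, seed=1,
        subpopulation=Subpopulation.NORTH,
    )
    south = gen_arrhenius_measurements(
        0.65, 20.0, ACCLIMATION_TEMPS, 0.0, 3, seed=2,
        subpopulation=Subpopulation.SOUTH,
    )
    return north + south


@pytest.fixture(scope="session")
def small_spec():
    """A 20x20 fine-cell coastal strip that coarsens to a 4x4 half-degree
    grid; two years of daily data keep the tests fast."""
    return ScenarioSpec(
        lat_bounds=(34.0, 36.0),
        lon_bounds=(-78.0, -76.0),
        fine_res_deg=0.1,
        coarsen_factor=5,
        years=(2001, 2002),
        seed=7,
    )
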