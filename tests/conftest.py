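import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from soyquefts import (NutrientTriple, Observation, QueftsParams,
                       SOYBEAN_SET_I)


@pytest.fixture(scope="session")
def set1_params() -> QueftsParams:
    """Engine parameters with the published Set-I envelope and 6 t/ha potential."""
    return QueftsParams(envelope=SOYBEAN_SET_I, ymax=6000.0)


@pytest.fixture
def full_observation() -> Observation:
    """A record carrying concentrations + weights, on a dry-matter basis."""
    return Observation(
        site_id="s1", year=2010, treatment="OPT",
        seed_yield=2312.14, straw_dm=2600.0,
        conc_seed=NutrientTriple(53.5, 7.2, 13.3),
        conc_straw=NutrientTriple(8.9, 3.2, 8.4),
        hi=0.46)
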