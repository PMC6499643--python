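import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cancereffects.catalog import synthetic_signature_catalog
from cancereffects.genes import toy_exome
from cancereffects.simulate import CohortConfig, PlantedDriver, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def models():
    return toy_exome()


@pytest.fixture(scope="session")
def sigs():
    return synthetic_signature_catalog()


def _pick_missense(model, row_index=150):
    missense = model.sites[model.sites["consequence"] == "missense"]
    s = missense.iloc[row_index]
    return int(s["pos"]), str(s["alt"])


@pytest.fixture(scope="session")
def small_cohort(models, sigs):
    """A mixed-strata cohort with planted drivers and DNV contamination."""
    pos1, alt1 = _pick_missense(models[0])
    pos2, alt2 = _pick_missense(models[1])
    config = CohortConfig(
        n_negative=90,
        n_positive=30,
        drivers=(
            PlantedDriver(models[0].gene, pos1, alt1, gamma=300.0),
            PlantedDriver(models[1].gene, pos2, alt2, gamma=800.0, scope="positive"),
        ),
        dnv_contamination_rate=0.05,
        seed=11,
    )
    return simulate_cohort(config, models, sigs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
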