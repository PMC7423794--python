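import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import drscreen as d
from drscreen.params import reference_fit

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tables():
    return d.default_transition_tables()


@pytest.fixture(scope="session")
def life_table():
    return d.synthetic_life_table()


@pytest.fixture(scope="session")
def ref_fits():
    return {t: reference_fit(t) for t in ("T1DM", "T2DM")}


@pytest.fixture(scope="session")
def model(tables, life_table, ref_fits):
    return d.TransitionModel(
        onset={t: d.WeibullOnset(f) for t, f in ref_fits.items()},
        tables=tables,
        life_table=life_table,
    )


@pytest.fixture(scope="session")
def strata():
    return {
        "T1DM": d.CohortStratum("T1DM", 22.7, {"hba1c": 8.7, "duration": 7.8}, 5003),
        "T2DM": d.CohortStratum("T2DM", 62.3, {"hba1c": 7.5, "duration": 4.2}, 86390),
    }


@pytest.fixture(scope="session")
def bundle(model, strata):
    return d.ModelBundle(
        model=model,
        costs=d.CostTable(),
        utilities=d.UtilityTable(),
        discount=d.DiscountSpec(0.035),
        strata=strata,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = d.GeneratorConfig.default(n_t1dm=150, n_t2dm=250)
    return d.generate_cohort(cfg, seed=42)
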