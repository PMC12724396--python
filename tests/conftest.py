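import numpy as np
import pytest

from hppeval import RunConfig, TruthParams, build_cohort, run_all


@pytest.fixture(scope="session")
def tiny_truth() -> TruthParams:
    """Small cohort: 8 cities, 4 countries, 15 years, strong HPP effect."""
    return TruthParams(
        n_cities=8,
        n_countries=4,
        years=(1999, 2013),
        hpp_year={"C01": 2004, "C02": 2006, "C03": 2008, "C04": 2005},
        hpp_effect=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_truth):
    return build_cohort(tiny_truth)


@pytest.fixture(scope="session")
def tiny_run(tiny_cohort):
    """One full pipeline execution on the tiny cohort, shared across tests."""
    cfg = RunConfig(n_samples=120, seed=7)
    return run_all(cfg, cohort=tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
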