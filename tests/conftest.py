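import numpy as np
import pytest

from trendimpact import (
    SimulationConfig,
    builtin_table1,
    fit_baseline,
    gen_panel,
    paper_like_fixture,
    aggregate_round2,
    filter_round1,
)


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture(scope="session")
def linear_model(table1):
    return fit_baseline(table1, model_form="linear")


@pytest.fixture(scope="session")
def fixture_panel():
    """Study-like synthetic panel: series, spec, raw responses."""
    series, spec = paper_like_fixture(seed=7)
    round1, round2 = gen_panel(spec)
    return series, spec, round1, round2


@pytest.fixture(scope="session")
def fixture_drivers(fixture_panel):
    _, spec, round1, round2 = fixture_panel
    verdicts = filter_round1(round1)
    retained = set(verdicts.index[verdicts["retained"]])
    return aggregate_round2(
        [r for r in round2 if r.event_id in retained], spec.horizon
    )


@pytest.fixture
def small_config():
    return SimulationConfig(n_reps=2000, seed=11, horizon=(2021, 2022, 2023))
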