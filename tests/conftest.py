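import pytest

from hcc_cea import (
    ModelSettings,
    build_strategies,
    default_life_table,
    evaluate_arms,
    run_cohort,
)


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def arms():
    """Base-case strategy pair (atezo-bev, sorafenib)."""
    return build_strategies()


@pytest.fixture(scope="session")
def base_run():
    """Base-case outcomes and comparison, computed once per session."""
    out_ab, out_sor, cmp_ = evaluate_arms()
    return {"atezo_bev": out_ab, "sorafenib": out_sor, "cmp": cmp_}


@pytest.fixture(scope="session")
def base_traces(arms, settings, life_table):
    traces = {}
    for strat in arms:
        trace, outcome = run_cohort(strat, settings, life_table)
        traces[strat.name] = (trace, outcome)
    return traces
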