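import pytest

from bpcentiles import gamlss, pipeline, simulate


@pytest.fixture(scope="session")
def truth():
    return simulate.default_truth()


@pytest.fixture(scope="session")
def cohort_small():
    return simulate.simulate_cohort(simulate.SimulationConfig(n=4000, seed=101))


@pytest.fixture(scope="session")
def analysis_small(cohort_small):
    analysis, report = pipeline.apply_exclusions(cohort_small)
    return analysis


@pytest.fixture(scope="session")
def cohort_large():
    return simulate.simulate_cohort(simulate.SimulationConfig(n=50000, seed=202))


@pytest.fixture(scope="session")
def quick_control():
    return gamlss.Control(n_knots=8, edf_grid=(1, 2, 3))


@pytest.fixture(scope="session")
def fit_small_sbp(analysis_small, quick_control):
    boys = analysis_small[analysis_small["sex"] == "M"]
    return gamlss.fit(boys, "sbp", gamlss.ModelSpec(), quick_control, scope="M/SBP")


@pytest.fixture(scope="session")
def fit_small_dbp(analysis_small, quick_control):
    boys = analysis_small[analysis_small["sex"] == "M"]
    return gamlss.fit(boys, "dbp", gamlss.ModelSpec(family="BCPE"), quick_control,
                      scope="M/DBP")
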