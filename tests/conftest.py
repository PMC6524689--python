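import pytest

from stopsig import pipeline, task


@pytest.fixture(scope="session")
def default_design() -> task.TaskDesign:
    return task.TaskDesign()


@pytest.fixture(scope="session")
def clean_params() -> task.RaceModelParams:
    """Race parameters without slowing, errors or omissions."""
    return task.RaceModelParams(
        go_mu_ms=330.0, go_sigma_ms=28.0, go_tau_ms=78.0, ssrt_mean_ms=250.0, ssrt_sd_ms=20.0
    )


@pytest.fixture(scope="session")
def rich_params() -> task.RaceModelParams:
    """Race parameters with slowing, choice errors and omissions."""
    return task.RaceModelParams(
        go_mu_ms=330.0,
        go_sigma_ms=28.0,
        go_tau_ms=78.0,
        ssrt_mean_ms=250.0,
        ssrt_sd_ms=20.0,
        slowing_factor=1.3,
        choice_error_rate=0.02,
        omission_rate=0.01,
    )


@pytest.fixture(scope="session")
def session(default_design, rich_params) -> task.SessionResult:
    return task.simulate_session(default_design, rich_params, 42)


@pytest.fixture(scope="session")
def tiny_design() -> task.TaskDesign:
    return task.TaskDesign(n_trials=48, stop_fraction=0.25, n_choice_trials=8)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_design) -> list[task.SessionResult]:
    specs, variation = task.study_cohort_spec()
    return task.simulate_cohort(specs, 2, tiny_design, 5, variation)


@pytest.fixture(scope="session")
def fixture_csv(tmp_path_factory):
    return pipeline.make_fixtures(0, tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def study_cohort():
    """One paper-scale cohort (30 per group, both effectors)."""
    specs, variation = task.study_cohort_spec()
    return task.simulate_cohort(specs, 30, task.TaskDesign(), 11, variation)
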