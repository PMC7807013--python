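import logging
import warnings

import pytest

from partmig.pipeline import AnalysisConfig, run_pipeline
from partmig.simulate import SimulationConfig, generate_cohort


def pytest_configure(config):
    logging.disable(logging.WARNING)
    warnings.filterwarnings("ignore", category=UserWarning)
    warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (100 individuals x 5 years = 500 bird-years)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_report(default_cohort):
    cfg = AnalysisConfig(simulation=SimulationConfig(seed=1), seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture(scope="session")
def truth_strategy(default_cohort):
    _, truth = default_cohort
    return {(r.bird_id, r.year): r.strategy for r in truth.bird_years.itertuples()}
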