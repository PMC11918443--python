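import warnings

import numpy as np
import pytest

from adstage.pipeline import PipelineConfig, run_all
from adstage.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def planted_cohort(default_spec):
    """One planted cohort (seed 1) shared across tests."""
    from dataclasses import replace

    from adstage.pipeline import stage_seed

    spec = replace(default_spec, seed=stage_seed(1, "simulate"))
    cohort, truth = generate_cohort(spec)
    return spec, cohort, truth


@pytest.fixture(scope="session")
def pipeline_result(default_spec):
    """One full pipeline run (seed 1) shared across integration tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(PipelineConfig(spec=default_spec, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
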