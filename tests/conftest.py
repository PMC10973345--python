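import numpy as np
import pytest

from gestri import (
    CohortConfig,
    DegreeSearchConfig,
    PipelineConfig,
    ResampleConfig,
    bin_into_periods,
    generate_cohort,
    load_canonical_parameters,
    run_pipeline,
)

#: published median-SCr polynomial, ascending powers
CANONICAL_COEFFS = (56.7, -0.223, -0.113, 0.00545, -0.0000653)


@pytest.fixture(scope="session")
def params():
    return load_canonical_parameters()


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=1234))


@pytest.fixture(scope="session")
def default_periods(default_cohort):
    return bin_into_periods(default_cohort)


@pytest.fixture(scope="session")
def fast_pipeline_config(tmp_path_factory):
    """Study-sized cohort but a reduced retry/repeat budget to keep runs quick."""
    return PipelineConfig(
        cohort=CohortConfig(),
        resample=ResampleConfig(max_attempts=40),
        search=DegreeSearchConfig(repeats=100),
        seed=20240901,
        out_dir=str(tmp_path_factory.mktemp("pipeline")),
    )


@pytest.fixture(scope="session")
def pipeline_result(fast_pipeline_config):
    return run_pipeline(fast_pipeline_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
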