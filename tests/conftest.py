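import pytest

from seedcerna.pipeline import PipelineConfig, run_pipeline
from seedcerna.simulate import SimConfig, simulate, write_fixture


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (seed 42) shared across the suite."""
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def fixture_dir(dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(dataset, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(dataset, fixture_dir):
    """(report, artifacts) of a full default run on the shared fixture."""
    return run_pipeline(fixture_dir, PipelineConfig())
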