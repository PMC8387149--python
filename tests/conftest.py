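import numpy as np
import pytest

from flyburst import RunConfig, make_fixture_suite, run_pipeline

#: root seed of the packaged fixture suite; the golden tables under
#: tests/data/golden were produced by one reference run at this seed
GOLDEN_SEED = 7

#: the hand-traceable 7-spike train: two bursts separated by a 0.2 s gap
SEVEN_SPIKES = [0.00, 0.05, 0.10, 0.30, 0.35, 0.40, 0.45]


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Synthetic fixture suite generated once per session at the golden seed."""
    out = tmp_path_factory.mktemp("suite")
    return make_fixture_suite(GOLDEN_SEED, out)


@pytest.fixture(scope="session")
def pipeline_run(fixture_suite):
    """One full pipeline run on the fixture suite: (config, tables)."""
    config = RunConfig.from_yaml(fixture_suite["config"])
    tables = run_pipeline(config)
    return config, tables


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
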