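import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fvtlda.pipeline import build_pipeline_data
from fvtlda.simulate import FixtureConfig, generate
from fvtlda.validation import SYNTHETIC_PARAMS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dataset():
    """Default planted-structure dataset, seed 1."""
    return generate(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_data(fixture_dataset):
    """Full deterministic pipeline output at the synthetic-study parameters."""
    ds = fixture_dataset
    return build_pipeline_data(ds.md, ds.ml, ds.ld, ds.mesh, params=SYNTHETIC_PARAMS)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
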