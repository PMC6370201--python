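import numpy as np
import pytest
from hypothesis import settings

from dyadsync import AnalysisConfig, GeneratorParams, SmoothingSpec, TransformSpec, make_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def dataset(params):
    """Default 60-dyad validation dataset (10 sync + 10 nosync, 3 conditions)."""
    return make_dataset(params, n_sync=10, n_nosync=10, seed=0)


@pytest.fixture(scope="session")
def artificial_dyads(dataset):
    return [d for d in dataset if d.condition == "artificial"]


@pytest.fixture(scope="session")
def best_config() -> AnalysisConfig:
    """WCLC, log-transformed, unsmoothed, bandwidth 125, cutoff .25 — one of
    the two configurations the validation singles out as best."""
    return AnalysisConfig(
        method="WCLC",
        transform=TransformSpec("log1p"),
        smoothing=SmoothingSpec("none"),
        bandwidth=125,
        r2_cutoff=0.25,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
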