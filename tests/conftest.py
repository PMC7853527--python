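import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from frrfprod.pipeline import PipelineConfig, run_pipeline
from frrfprod.phimodel import default_schemes, stratified_bootstrap
from frrfprod.synthetic import SyntheticScenario, generate_campaign


@pytest.fixture(scope="session")
def noise_free_result():
    """Full pipeline run on the exactly-invertible noise-free campaign."""
    config = PipelineConfig(
        scenario=SyntheticScenario.noise_free(seed=1),
        rank_submodels=False,
        run_gpp=True,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def default_campaign():
    """One default (noisy) campaign: (frrf, profiles, incubations, truth)."""
    return generate_campaign(SyntheticScenario(seed=7))


@pytest.fixture(scope="session")
def default_bootstrap(default_campaign):
    _, _, _, truth = default_campaign
    return stratified_bootstrap(truth, default_schemes(), seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
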