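import numpy as np
import pytest

from commtrial import ArmSummary, PosteriorSettings, VariancePrior


@pytest.fixture(scope="session")
def vprior() -> VariancePrior:
    """Default residual-variance prior (weight 1, central SD 0.07)."""
    return VariancePrior()


@pytest.fixture(scope="session")
def gibbs_settings() -> PosteriorSettings:
    return PosteriorSettings(estimator="gibbs_rao_blackwell", seed=20240)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(915)


def make_arm(rng: np.random.Generator, n: int, mean: float, sd: float = 0.07) -> ArmSummary:
    return ArmSummary.from_samples(rng.normal(mean, sd, size=n))
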