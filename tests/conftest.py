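import numpy as np
import pytest
from hypothesis import settings

from copuladeg import FoldChangeMatrix, ModelParams

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def theta_mixed() -> ModelParams:
    """Asymmetric three-component parameters used across oracle tests."""
    return ModelParams(
        pi=(0.5, 0.3, 0.2), mu1=1.0, mu2=-1.0, sigma1=1.0, sigma2=1.0,
        rho1=0.8, rho2=0.8,
    )


@pytest.fixture
def theta_symmetric() -> ModelParams:
    return ModelParams(
        pi=(0.5, 0.25, 0.25), mu1=2.0, mu2=-2.0, sigma1=1.0, sigma2=1.0,
        rho1=0.6, rho2=0.6,
    )


@pytest.fixture
def theta_generic() -> ModelParams:
    """Deliberately un-symmetric parameters (different sigmas and rhos)."""
    return ModelParams(
        pi=(0.55, 0.25, 0.2), mu1=1.7, mu2=-2.2, sigma1=0.9, sigma2=1.3,
        rho1=0.75, rho2=0.55,
    )


@pytest.fixture
def small_data() -> FoldChangeMatrix:
    rng = np.random.default_rng(42)
    values = rng.normal(size=(20, 2))
    ids = np.array([f"g{i}" for i in range(20)])
    return FoldChangeMatrix(gene_ids=ids, values=values)
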