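import numpy as np
import pytest

from cogtomo import (
    FeatureSpace,
    ObserverParams,
    SubjectiveDistribution,
)


@pytest.fixture(scope="session")
def space() -> FeatureSpace:
    return FeatureSpace()


@pytest.fixture(scope="session")
def std_gaussian(space) -> SubjectiveDistribution:
    """Single standard Gaussian at the origin (rotationally symmetric)."""
    return SubjectiveDistribution(
        space, np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None]
    )


@pytest.fixture(scope="session")
def bimodal(space) -> SubjectiveDistribution:
    """Equal-weight components at (+/-2, 0) with covariance 0.5 I: a clearly
    bimodal truth whose modes sit 4 SD apart."""
    return SubjectiveDistribution(
        space,
        np.array([0.5, 0.5]),
        np.array([[-2.0, 0.0], [2.0, 0.0]]),
        np.stack([0.5 * np.eye(2)] * 2),
    )


@pytest.fixture(scope="session")
def gen_params() -> ObserverParams:
    """Observer parameters used by the synthetic subjects throughout."""
    return ObserverParams(perceptual_sigma=0.5, temperature=3.0, lapse=0.05)
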