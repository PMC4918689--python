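import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k2_model():
    """A small 2-channel product HMM with well-separated emissions."""
    from phmmdfc import EmissionParams, ProductHMMModel

    return ProductHMMModel(
        k=2,
        startprob=np.array([0.4, 0.3, 0.2, 0.1]),
        transmat=np.array([
            [0.70, 0.10, 0.10, 0.10],
            [0.05, 0.80, 0.05, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.25, 0.25, 0.25, 0.25],
        ]),
        emissions=EmissionParams(means=[[-0.5, 0.4], [-0.3, 0.6]],
                                 stds=[[0.2, 0.25], [0.15, 0.3]]),
    )
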