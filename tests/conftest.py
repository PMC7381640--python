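import numpy as np
import pytest

from radsurvey.forward import DetectorModel
from radsurvey.hpge import synthetic_efficiency_curve
from radsurvey.spectrometry import build_response_matrix, default_binning
from radsurvey.synthetic import RegionTruth, TruthConfig, default_truth_config


@pytest.fixture(scope="session")
def truth_config():
    return default_truth_config(seed=42)


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def response(detector):
    return build_response_matrix(detector, default_binning())


@pytest.fixture(scope="session")
def efficiency_curve():
    return synthetic_efficiency_curve()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_region_config(
    mean, sd, seed=0, sf_carbody=2.01, sf_asphalt=0.96, **kwargs
) -> TruthConfig:
    """One-region campaign truth used by recovery tests."""
    region = RegionTruth(
        mean=tuple(mean), sd=tuple(sd), weight=1.0,
        bbox=(10.0, 12.0, 105.0, 107.0),
        sf_carbody=sf_carbody, sf_asphalt=sf_asphalt,
    )
    return TruthConfig(regions={"only": region}, seed=seed, **kwargs)
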