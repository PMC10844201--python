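import numpy as np
import pytest

from ednabycatch.calibration import CalibrationModel
from ednabycatch.metabarcoding import bundled_references
from ednabycatch.synthetic import GeneratorConfig, generate_calibration_design


@pytest.fixture(scope="session")
def references():
    return bundled_references()


@pytest.fixture()
def identity_model():
    """alpha=0, beta=1, huge phi: invert and predict are the identity map."""
    return CalibrationModel(alpha=0.0, beta_slope=1.0, phi=1e9, season="March", water_type="factory")


@pytest.fixture(scope="session")
def november_samples():
    """One simulated November-design calibration dataset (11 ratios x 9 reps)."""
    config = GeneratorConfig(seed=20211101, alpha=-0.4, beta=1.0, phi=50.0)
    return generate_calibration_design(config)


def make_model(alpha, beta_slope, phi=200.0, season="March", water_type="factory", vcov=None):
    return CalibrationModel(
        alpha=alpha,
        beta_slope=beta_slope,
        phi=phi,
        season=season,
        water_type=water_type,
        vcov=np.zeros((3, 3)) if vcov is None else vcov,
    )
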