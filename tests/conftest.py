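import numpy as np
import pytest

from filmcal import CalibrationParams


@pytest.fixture
def mean_params() -> CalibrationParams:
    """Inter-day mean response curve of the reference film/scanner system."""
    return CalibrationParams(245.0, 3271.0, 31.7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_valid_params(rng: np.random.Generator) -> CalibrationParams:
    """A physically plausible random response curve."""
    return CalibrationParams(
        P0=rng.uniform(200, 300),
        Ps=rng.uniform(2500, 4000),
        m=rng.uniform(25, 45),
    )
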