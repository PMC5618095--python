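import numpy as np
import pytest

from chromval import PrepProtocol, ResponseModel, StudyDesign


@pytest.fixture
def prep():
    """The 0.5 g / 10 mL extraction protocol."""
    return PrepProtocol()


@pytest.fixture
def clean_response():
    """Noise-free linear response, slope 50, zero intercept."""
    return ResponseModel(slope=50.0, intercept=0.0, injection_cv=0.0)


@pytest.fixture
def default_design():
    """The fortified-study design at its published-condition defaults."""
    return StudyDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
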