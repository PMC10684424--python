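import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_calibrated_model  # noqa: E402


@pytest.fixture(scope="session")
def calibrated_model():
    """One realistic calibrated model shared across tests."""
    return make_calibrated_model(seed=7)


@pytest.fixture(scope="session")
def calibrated_model_scaled(calibrated_model):
    """The same model with all fracture incidence scaled by 0.55."""
    return calibrated_model.scaled_incidence(0.55)
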