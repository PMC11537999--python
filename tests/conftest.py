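import numpy as np
import pytest
from hypothesis import settings

from qhts.synthetic import ScreenConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def default_config():
    """Generator config at the assay's nominal plate statistics."""
    return ScreenConfig(n_compounds=100, rng_seed=42)


@pytest.fixture
def quiet_config():
    """Noise-free generator config (no planted actives)."""
    return ScreenConfig(
        n_compounds=50,
        dmso_cv=0.0,
        fraction_true_antagonists=0.0,
        fraction_cytotoxic=0.0,
        pos_control_cv=0.0,
        rng_seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
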