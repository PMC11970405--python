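import numpy as np
import pandas as pd
import pytest

from ptcscreen import synthetic


@pytest.fixture
def noise_free_growth():
    return synthetic.GrowthParams(measurement_noise_cv=0.0)


@pytest.fixture
def toy_outcomes():
    """Six treatments with a hand-checkable class structure."""
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(6)],
        "sample_id": [f"S{i}" for i in range(6)],
        "regimen": ["r"] * 6,
        "pA": [0.2, 0.4, 0.75, 0.9, 1.1, 1.4],
        "recist": ["CR/PR", "PR", "SD", "SD", "PD", "PD"],
        "prospective": [True, False, True, False, True, False],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
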