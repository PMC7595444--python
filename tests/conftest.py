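import numpy as np
import pytest

from arvarsim import VARModel


@pytest.fixture
def ar_truth():
    """Purely autoregressive truth (O = 0), p = 3."""
    return VARModel(phi=np.diag([0.5, 0.3, 0.4]), noise_vars=np.ones(3),
                    model_id="ar_truth")


@pytest.fixture
def var_truth():
    """Truth with cross-lagged effects: D = 0.3, O = 0.05, p = 6."""
    p = 6
    phi = np.full((p, p), 0.05)
    np.fill_diagonal(phi, 0.3)
    return VARModel(phi=phi, noise_vars=np.ones(p), model_id="var_truth")


def equal_offdiag_model(p: int, d: float, o: float, model_id: str = "") -> VARModel:
    """Matrix with constant diagonal d and constant off-diagonal o."""
    phi = np.full((p, p), o)
    np.fill_diagonal(phi, d)
    return VARModel(phi=phi, noise_vars=np.ones(p), model_id=model_id)
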