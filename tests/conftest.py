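import numpy as np
import pytest

from pyramidal import HomeostasisParams, TransferParams


@pytest.fixture(scope="session")
def transfer():
    """Reference transfer-function parameter set."""
    return TransferParams(theta_p0=0.0, theta_p1=-1.0, theta_d=0.0, alpha=0.3)


@pytest.fixture(scope="session")
def homeo():
    """Reference homeostasis parameter set."""
    return HomeostasisParams(
        mu_b=1e-3, mu_n=1e-4, mu_av=5e-3,
        I_p_target=0.0, I_d_target=0.0, V_p_target=0.25, V_d_target=0.25,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
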