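import numpy as np
import pytest

from t2ivim import (
    FitConfig,
    T2IVIMParams,
    protocol1,
    protocol2,
    simulate_series,
)


@pytest.fixture
def liver_params():
    """Healthy-liver-like ground truth: blood T2 > tissue T2."""
    return T2IVIMParams(
        S0=100.0, f=0.137, D=1.07e-3, Dstar=0.153, T2p=77.6, T2t=42.1
    )


@pytest.fixture
def p1():
    return protocol1()


@pytest.fixture
def p2():
    return protocol2()


@pytest.fixture
def noiseless_p2_series(liver_params, p2):
    return simulate_series(liver_params, p2, SNR=np.inf)


@pytest.fixture
def noiseless_p1_series(liver_params, p1):
    return simulate_series(liver_params, p1, SNR=np.inf)


@pytest.fixture
def default_config():
    return FitConfig()
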