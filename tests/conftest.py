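import numpy as np
import pytest


@pytest.fixture(scope="session")
def myo():
    """Shipped calibrated epicardial myocardial cell parameters."""
    from cardiomp import config as cfg

    return cfg.myocardial_params()


@pytest.fixture(scope="session")
def endo(myo):
    from cardiomp.cell import AP_ENDO

    return myo.with_(a=AP_ENDO)


@pytest.fixture(scope="session")
def purkinje():
    from cardiomp import config as cfg

    return cfg.purkinje_params()


@pytest.fixture(scope="session")
def sigma_f():
    from cardiomp import config as cfg

    return cfg.load_defaults()["tissue"]["sigma_f"]


@pytest.fixture(scope="session")
def single_ap_trace(myo):
    """One paced action potential of the calibrated epicardial cell."""
    from cardiomp.cell import StimulusProtocol, integrate_cell

    stim = StimulusProtocol(period=None, n_pulses=1)
    return integrate_cell(myo, stim, duration=900.0, rtol=1e-7, atol=1e-9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
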