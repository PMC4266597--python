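import numpy as np
import pytest

import forcespec as fs


@pytest.fixture(scope="session")
def frc_params():
    """QM-FRC parameters without the backbone-stretch correction."""
    return fs.PolymerParams(qm_correction=None)


@pytest.fixture(scope="session")
def wlc_params():
    return fs.PolymerParams(model=fs.ChainModel.WLC, persistence_length=0.38,
                            qm_correction=None)


@pytest.fixture(scope="session")
def dataset_1600():
    """200 configuration-I traces at 1600 nm/s, fixed seed; shared by the
    detection / loading-rate / classification ground-truth tests."""
    system = fs.default_system()
    protocol = fs.ProtocolSpec(pulling_speed=1600.0, seed=42)
    curves, logs, truth = fs.simulate_dataset(system, protocol, 200)
    return curves, logs, truth
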