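import numpy as np
import pytest

from spleendce import (
    AcquisitionProtocol,
    EnhancementModel,
    SignalTimeCurve,
    StageCalibration,
    sample_curve,
)


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def calibration() -> StageCalibration:
    return StageCalibration()


@pytest.fixture()
def model() -> EnhancementModel:
    """A mid-range spleen model whose wash-in and wash-out extrema both lie
    well inside the acquisition window."""
    return EnhancementModel(s_base=100.0, t_onset=10.0, t_peak_offset=50.0,
                            amplitude=80.0, shape_alpha=3.0,
                            washout_fraction=0.6)


@pytest.fixture()
def noiseless_curve(model, protocol) -> SignalTimeCurve:
    t, s = sample_curve(model, protocol)
    return SignalTimeCurve(t, s)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
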