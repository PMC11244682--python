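import numpy as np
import pytest

from eslope import CalibrationModel, PercentCurve, ScanCurve


@pytest.fixture
def toy_pcurve() -> PercentCurve:
    """Hand-checkable percent curve: maximum 100 at 1.0 cm, exactly linear
    descent value = 100 - 50*(z - 1) down to 5% at 2.9 cm, constant 3% tail.

    Closed forms: d_max = 1.0, d70 = 1.6, d30 = 2.4, I50 = 2.0,
    descent gradient = -50 %/cm, Rp = (150 - 3)/50 = 2.94 cm.
    """
    build_z = np.array([0.0, 0.25, 0.5, 0.75])
    build_v = np.array([70.0, 85.0, 95.0, 99.0])
    desc_z = np.arange(1.0, 2.95, 0.1)  # 1.0 .. 2.9
    desc_v = 100.0 - 50.0 * (desc_z - 1.0)
    tail_z = np.array([3.0, 3.2, 3.4, 3.6, 3.8])
    tail_v = np.full_like(tail_z, 3.0)
    return PercentCurve(
        np.concatenate([build_z, desc_z, tail_z]),
        np.concatenate([build_v, desc_v, tail_v]),
    )


@pytest.fixture
def toy_scan(toy_pcurve) -> ScanCurve:
    """The toy curve as a raw scan in arbitrary units (x 0.8)."""
    return ScanCurve(toy_pcurve.depths, 0.8 * toy_pcurve.values)


@pytest.fixture
def energy_model() -> CalibrationModel:
    """Published slope-to-energy calibration: E = 32.311*exp(0.0247*M)."""
    return CalibrationModel(amplitude_a=32.311, rate_b=0.0247, kind="energy")


@pytest.fixture
def i50_model() -> CalibrationModel:
    """Published slope-to-I50 calibration: I50 = 13.714*exp(0.0246*M)."""
    return CalibrationModel(amplitude_a=13.714, rate_b=0.0246, kind="i50")
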