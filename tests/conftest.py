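import numpy as np
import pytest

from paleospd import (
    CalendarWindow,
    CalibrationCurve,
    RegionConfig,
    identity_curve,
    interpolate_curve,
)


@pytest.fixture(scope="session")
def ident_curve() -> CalibrationCurve:
    """Annual identity curve (μ(t) = t, σ_curve = 0) spanning -150..2600 BP."""
    return identity_curve(-150, 2600)


@pytest.fixture(scope="session")
def toy_curve() -> CalibrationCurve:
    """5-point toy curve interpolated to an annual grid."""
    raw = CalibrationCurve(
        cal_bp=np.array([0, 10, 20, 30, 40]),
        c14_age=np.array([50.0, 80.0, 90.0, 150.0, 200.0]),
        sigma_curve=np.array([5.0, 5.0, 10.0, 5.0, 5.0]),
        name="toy",
    )
    return interpolate_curve(raw)


@pytest.fixture(scope="session")
def study_window() -> CalendarWindow:
    return CalendarWindow(start_bp=1750, end_bp=150)


@pytest.fixture(scope="session")
def region_config() -> RegionConfig:
    return RegionConfig()
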