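import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phagekit.io_tables import GrowthCurve, KillCurvePanel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def logistic_control():
    """Noiseless logistic control curve: r=0.7/h, K reached around 20 h."""
    t = np.arange(0.0, 49.0)
    k, n0, r = 1.0, 1e-5, 0.7
    od = k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))
    return GrowthCurve(t, od, label="control")


@pytest.fixture
def flat_panel():
    """Panel whose phage curves are exact copies of the control."""
    t = np.arange(0.0, 11.0)
    od = np.linspace(0.01, 1.0, t.size)
    control = GrowthCurve(t, od, label="control")
    curves = [
        (moi, GrowthCurve(t, od.copy(), label=f"{moi:g}"))
        for moi in (0.001, 0.1, 10.0, 1000.0)
    ]
    return KillCurvePanel(control=control, phage_curves=curves)
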