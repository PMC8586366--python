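import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bindkit.datatypes import TitrationSeries

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

UM = 1e-6


@pytest.fixture
def linear_quench_series() -> TitrationSeries:
    """Noiseless static-quenching series: F = 1000/(1 + 5000 [Q])."""
    q = np.arange(0, 49, 8) * UM
    return TitrationSeries(
        series_id="BSA", temperature=298.15,
        quencher_conc=q, signal=1000.0 / (1.0 + 5000.0 * q),
    )


@pytest.fixture
def flat_series() -> TitrationSeries:
    q = np.arange(0, 49, 8) * UM
    return TitrationSeries(
        series_id="flat", temperature=298.15,
        quencher_conc=q, signal=np.full(q.size, 750.0),
    )
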