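import numpy as np
import pytest

from duskmetrics.dam import DaySpec, LightSchedule, MonitorData, monitor_from_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def ld_schedule():
    return LightSchedule(lights_on_hr=8.0, days=[DaySpec(), DaySpec()])


@pytest.fixture
def two_day_monitor(rng) -> MonitorData:
    """Two whole days of Poisson counts on 4 channels, starting at lights-on."""
    counts = rng.poisson(2.0, size=(2880, 4))
    return monitor_from_counts(counts)
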