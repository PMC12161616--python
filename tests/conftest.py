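import numpy as np
import pytest

from wheelpa import synthetic_data as sd
from wheelpa.daily_metrics import ThresholdConfig
from wheelpa.minute_features import Demographics

# A short awake window keeps full-pipeline renders cheap; the minute grid
# is still the full 1440 slots.
SHORT_PARAMS = sd.ScheduleParams(
    waketime_minute=8 * 60,
    bedtime_minute=14 * 60,
    proportions=(0.5, 0.3, 0.2),
)


@pytest.fixture(scope="session")
def thresholds() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def person() -> Demographics:
    return Demographics(mass_kg=75.0)


@pytest.fixture(scope="session")
def short_schedule() -> sd.ActivitySchedule:
    return sd.generate_schedule(SHORT_PARAMS, n_days=1, seed=11)[0]


@pytest.fixture(scope="session")
def full_battery_device() -> sd.DeviceProfile:
    return sd.DeviceProfile(battery_life_h=24.0, noise_sd_g=0.0)


@pytest.fixture(scope="session")
def rendered_day(short_schedule, full_battery_device):
    """Noise-free render of the short schedule, full battery."""
    return sd.render_streams(short_schedule, full_battery_device, seed=5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
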