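import numpy as np
import pytest

from aquamet import FishRecord, RespirometryProtocol
from aquamet.synthetic import TraceTruth


@pytest.fixture
def fish():
    """2.2 kg fish in the study's 54.5 l respirometer."""
    return FishRecord(
        fish_id="f1", sex="female", treatment="sham",
        body_mass=2.2, fork_length=55.7, respirometer_volume=54.5,
    )


@pytest.fixture
def protocol():
    """Study schedule: 4-min first measurement, then 15-min cycles
    (9 min flush + 6 min sealed) for ~20 h at 1 Hz."""
    return RespirometryProtocol()


@pytest.fixture
def short_protocol():
    """Three-hour schedule for fast end-to-end tests (17 cycles)."""
    return RespirometryProtocol(
        cycle_length=10.0, flush_length=6.0, measure_length=4.0,
        first_measure_length=4.0, total_duration_h=3.0,
    )


@pytest.fixture
def truth():
    return TraceTruth(rmr_true=2.96, mmr_true=11.94, k_recovery=0.05)


@pytest.fixture
def clean_truth():
    """No noise, no drift, no spontaneous-activity jitter."""
    return TraceTruth(
        rmr_true=2.96, mmr_true=11.94, k_recovery=0.05,
        noise_sd=0.0, activity_cv=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)
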