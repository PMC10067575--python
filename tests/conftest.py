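import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ecogkit.pipeline import AnalysisParams
from ecogkit.synthetic import BackgroundSpec, DrugEffectSpec, SpikeSpec, gen_session

#: parameters for scaled-down sessions used throughout the suite
SCALED = dict(half_duration_s=125.0, sample_rate_hz=500.0,
              acclimation_s=5.0, block_len_s=120.0)


@pytest.fixture(scope="session")
def scaled_params() -> AnalysisParams:
    return AnalysisParams(acclimation_s=SCALED["acclimation_s"],
                          block_len_s=SCALED["block_len_s"], qc_min_epochs=10)


@pytest.fixture(scope="session")
def scaled_session():
    """One short synthetic session with a planted drug effect."""
    rec, manifest = gen_session(
        BackgroundSpec(duration_s=SCALED["half_duration_s"],
                       sample_rate_hz=SCALED["sample_rate_hz"]),
        SpikeSpec(rate_per_min=15.0),
        None,
        DrugEffectSpec(power_scale=0.5, spike_rate_multiplier=0.4),
        seed=11,
    )
    return rec, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
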