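import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cavbep

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free():
    """40 s paced recording without any noise source; the extraction
    oracle fixture."""
    params = cavbep.SynthParams(duration_s=40.0, noise_sd=0.0, stv_sigma_ms=0.0)
    rec, gt = cavbep.synth_recording(params)
    return params, rec, gt


@pytest.fixture(scope="session")
def noise_free_beats(noise_free):
    _, rec, _ = noise_free
    return cavbep.detect_beats(rec)
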