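import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A deterministic 256-px, 2-filament truth image and its degradation."""
    import dwdc

    spec = dwdc.PhantomSpec(image_size_px=256, n_filaments=2, seed=1)
    truth = dwdc.generate_ground_truth(spec)
    degraded = dwdc.degrade(truth, dwdc.DegradationSpec(seed=11))
    return truth, degraded
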