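import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_kymogram():
    """Compacting kymogram, v = 2 px/frame, no noise, dye channel."""
    from condensate_quant import synthetic

    spec = synthetic.SyntheticKymogramSpec(
        n_frames=100, n_pixels=120, end_start=100.0,
        compaction_rate_v=2.0, dna_intensity=1.0, noise_sigma=0.0,
    )
    return synthetic.gen_kymogram(spec)


@pytest.fixture
def frap_field_centers():
    """Eight well-spread droplet centers (row, col) in a 128x128 field."""
    return [(20, 20), (20, 100), (60, 40), (60, 110),
            (100, 20), (100, 90), (40, 70), (90, 60)]


def approx_rel(a, b, rel):
    return abs(a - b) <= rel * abs(b)
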