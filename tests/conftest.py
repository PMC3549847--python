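import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_pair():
    """A tiny matched tumour/control profile pair over two chromosomes."""
    from convexcnv import DepthProfile, TargetRegion

    regions = [
        TargetRegion("chr1", 100, 300, "e1"),
        TargetRegion("chr1", 1000, 1200, "e2"),
        TargetRegion("chr1", 5000, 5300, "e3"),
        TargetRegion("chr2", 40, 240, "e4"),
        TargetRegion("chr2", 900, 1100, "e5"),
    ]
    control = DepthProfile(regions=regions, doc=[50.0, 40.0, 60.0, 55.0, 45.0],
                           sample_id="control")
    tumour = DepthProfile(regions=list(regions), doc=[48.0, 41.0, 61.0, 54.0, 46.0],
                          sample_id="tumour")
    return control, tumour
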