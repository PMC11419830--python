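import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ogmrepeat.labelmap import ReferenceLabelMap, build_locus
from ogmrepeat.simulate import make_locus_region

settings.register_profile(
    "ci",
    max_examples=30,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# hg38 marker geometry of the CTG18.1 locus on chromosome 18
UPSTREAM = 55_584_360
DOWNSTREAM = 55_594_648
COMPANION = 55_595_438


@pytest.fixture(scope="session")
def ctg18_map() -> ReferenceLabelMap:
    return ReferenceLabelMap(
        "chr18",
        56_000_000,
        ((10_414, UPSTREAM), (10_415, DOWNSTREAM), (10_416, COMPANION)),
    )


@pytest.fixture(scope="session")
def ctg18_locus(ctg18_map):
    return build_locus(ctg18_map, 10_414, 10_415, ref_repeat_count=24)


@pytest.fixture(scope="session")
def region():
    """Synthetic 1 Mb locus region mirroring the CTG18.1 marker geometry."""
    return make_locus_region()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
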