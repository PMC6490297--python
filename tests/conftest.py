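import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from recmotif import Background, make_bundle  # noqa: E402


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def small_bundle():
    """2 x 300 kb sim-like fixture with planted [CA]6, coupling b=0.5."""
    manifest = {
        "seed": 7,
        "chromosomes": [
            {"name": "chr1", "length": 300_000},
            {"name": "chr2", "length": 300_000},
        ],
        "landscape": {
            "shape": "sim_like",
            "noise_cv": 0.3,
            "edge_drop_width": 30_000,
        },
        "plant": {"motif": "[CA]6", "a": 0.2, "b": 0.5},
    }
    return make_bundle(manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
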