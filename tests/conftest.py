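import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def brownian_cells():
    """Ten cells of pure Brownian tracks with dwell long enough for lag 10."""
    import memprobe as mp

    cfg = mp.SPTSimConfig(
        seed=411, k_off_true=2.0, n_cells=10, tracks_per_cell=250,
    )
    return mp.simulate_membrane_spt(cfg)
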