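import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitskew as gs

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default-condition synthetic corpus: 102 straight + 108 skewed DJNPs."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = gs.generate_dataset(102, 108, out, master_seed=42)
    return out, manifest


@pytest.fixture(scope="session")
def straight_walk():
    """Noise-free straight walk at the default recording conditions."""
    return gs.simulate_walk(gs.WalkConfig(noise_sd=0.0), seed=7)


@pytest.fixture(scope="session")
def skewed_walk():
    """Noise-free walk drifting 8 degrees toward image right."""
    return gs.simulate_walk(gs.WalkConfig(noise_sd=0.0, skew_angle=8.0), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_djnp(rng, n_samples=6, frame_size=(1080, 1920)):
    """A DJNP of uniformly scattered points with random joint identities."""
    import pandas as pd
    from gaitskew.djnp import DJNP, POINT_COLUMNS, SourceMeta

    rows = []
    for i in range(n_samples):
        n_pts = int(rng.integers(3, 12))
        for _ in range(n_pts):
            rows.append(
                (
                    int(rng.integers(0, 18)),
                    i,
                    i * 0.3,
                    float(rng.uniform(0, frame_size[0] - 1)),
                    float(rng.uniform(0, frame_size[1] - 1)),
                )
            )
    pts = pd.DataFrame(rows, columns=POINT_COLUMNS)
    meta = SourceMeta(frame_width=frame_size[0], frame_height=frame_size[1])
    return DJNP(pts, n_samples, gs.COCO18, meta)
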