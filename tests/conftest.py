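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


@pytest.fixture(scope="session")
def small_insitu_sim():
    """One 64x64 responder simulation shared across tests (generation ~10 s)."""
    from gluimg.synthetic import HotspotConfig, MovieSpec, generate_insitu_movie

    spec = MovieSpec(width_px=64, height_px=64, seed=7)
    return generate_insitu_movie(spec, hotspot_config=HotspotConfig())


@pytest.fixture(scope="session")
def small_invivo_movie():
    """A small, quick in vivo movie with modest activity (no stimulus)."""
    from gluimg.synthetic import (
        ActivityConfig,
        MotionConfig,
        default_invivo_spec,
        generate_invivo_movie,
    )

    spec = default_invivo_spec(width_px=64, height_px=64, duration_s=20.0, seed=11)
    return generate_invivo_movie(
        spec,
        activity_config=ActivityConfig(n_regions=10),
        motion_config=MotionConfig(jitter_sd_px=0.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
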