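import numpy as np
import pytest

import uwbradar as u


@pytest.fixture(scope="session")
def short_plan():
    """0.5-2.5 m acquisition window (288 bins), PII 12, 50 Hz."""
    return u.derive_timing(u.DesiredRange(0.5, 2.5))


@pytest.fixture(scope="session")
def full_plan():
    """0.5-5.5 m acquisition window (576 bins)."""
    return u.derive_timing(u.DesiredRange(0.5, 5.5))


@pytest.fixture(scope="session")
def resting_scene():
    """Resting subject at 2 m plus strong static clutter, default noise."""
    return u.SceneScript(
        actors=(
            u.Actor(kind="stationary_subject", base_range=2.0),
            u.Actor(kind="static_clutter", base_range=1.0, reflectivity=10.0),
        ),
        duration=60.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def resting_scan(resting_scene, short_plan):
    scan, truth = u.render_scans(resting_scene, short_plan)
    return scan, truth


@pytest.fixture(scope="session")
def clutter_free_scan(resting_scan):
    scan, _ = resting_scan
    return u.svd_clutter_removal(u.apply_fasttime_filter(scan))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
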