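import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vdep_eeg import (
    SimConfig,
    extract_epochs,
    build_intervals,
    make_expert_tags,
    make_recordings,
    make_truth,
    resolve_tags,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    """A down-scaled simulation: 2 participants, 3 tagged + 1 filler trial."""
    return SimConfig(n_participants=2, n_videos=3, n_trials=4, seed=7)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """truth, recordings, expert tags and resolved timeline, one sim."""
    truth = make_truth(small_cfg)
    rec = make_recordings(small_cfg, truth)
    tags_a, tags_b = make_expert_tags(small_cfg, truth)
    timeline = resolve_tags(tags_a, tags_b)
    return {"cfg": small_cfg, "truth": truth, "rec": rec,
            "tags": (tags_a, tags_b), "timeline": timeline}


@pytest.fixture(scope="session")
def small_epochs(small_world):
    iv = build_intervals(small_world["timeline"], "colour")
    return extract_epochs(small_world["rec"], iv)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
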