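import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import listcensus as lc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_events(rows):
    """events DataFrame from (video_id, time_s, species, n_individuals) tuples."""
    return pd.DataFrame(rows, columns=["video_id", "time_s", "species", "n_individuals"])


def make_videos(rows):
    """videos DataFrame from (video_id, site_id, status, depth_class, duration_s)."""
    return pd.DataFrame(
        rows, columns=["video_id", "site_id", "status", "depth_class", "duration_s"]
    )


@pytest.fixture(scope="session")
def small_survey():
    """A modest simulated survey shared by read-only tests."""
    cfg = lc.SimConfig(n_videos_per_habitat=4, n_sites_per_status=2, arrival_rate_scale=0.5)
    events, videos, truth = lc.simulate_survey(cfg, seed=11)
    return events, videos, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
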