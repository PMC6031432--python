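"""Shared simulation fixtures (session-scoped: several tests read each run)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sizerkit.growthsim import SimConfig, default_feedback_windows, simulate
from sizerkit.track_stats import TrackSet


@pytest.fixture(scope="session")
def sizer_run():
    """Asynchronous sizer population, ~2000 cells at fixation."""
    cfg = SimConfig(g1_exit_rule="sizer", seed=101)
    return simulate(cfg, 42.0, 500, founder_stagger=21.0)


@pytest.fixture(scope="session")
def timer_run():
    """Size-independent G1 timer population (null for size sensing)."""
    cfg = SimConfig(g1_exit_rule="timer", seed=102)
    return simulate(cfg, 42.0, 500, founder_stagger=21.0)


@pytest.fixture(scope="session")
def feedback_run():
    """Timer population with the two default growth-feedback windows."""
    cfg = SimConfig(
        g1_exit_rule="timer", feedback_windows=default_feedback_windows(), seed=103
    )
    return simulate(cfg, 42.0, 750, founder_stagger=21.0, record_bulk=False)


@pytest.fixture(scope="session")
def sizer_tracks(sizer_run):
    return TrackSet(sizer_run.track_samples, sizer_run.track_events)


@pytest.fixture(scope="session")
def timer_tracks(timer_run):
    return TrackSet(timer_run.track_samples, timer_run.track_events)


def make_null_snapshot(n: int, seed: int) -> pd.DataFrame:
    """Synthetic snapshot with no size->cycle coupling (phases independent of size)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(0.0, 21.0, n)
    size = 100.0 + 5.0 * age + rng.normal(0.0, 15.0, n)
    p_post = np.clip((age - 5.0) / 12.0, 0.02, 0.98)  # age-dependent, size-independent
    phase = np.where(rng.uniform(size=n) < p_post, "postG1", "G1").astype(object)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "age_h": age,
            "size_au": size,
            "nucleus_au": size,
            "phase": phase,
        }
    )
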