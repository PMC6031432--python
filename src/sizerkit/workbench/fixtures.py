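"""Deterministic scenario datasets for testing and demonstration.

Each scenario parameterizes the simulator (or an exact analytic
construction) to mirror one class of size-homeostasis experiment:

``null_timer``
    Size-independent G1 timer, no growth feedback: the negative control
    in which birth size and G1 length are uncoupled and size variance can
    only grow with age.
``sizer``
    G1 size threshold (the default configuration): small-born cells wait
    longer in G1; the snapshot shows the post-G1 > G1 contrast and the
    G1 mean-size plateau.
``feedback_dips``
    Timer cycle plus two age windows of negative size→growth feedback:
    the G_cv curve develops two negative excursions.
``rapamycin_like``
    Growth-rate inhibition (growth scale 0.4) switched on mid-run in a
    sizer population: cycle length compensates, buffering cell size.
``sns_like``
    Cycle slow-down (durations ×2) switched on mid-run in a sizer
    population: growth per cycle compensates via the size threshold.
``perfect_compensation_panel``
    Analytic bulk panel with v = C/τ exactly: the log–log compensation
    correlation equals -1 and every condition shares one target size.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..growthsim import (
    Perturbation,
    SimConfig,
    default_feedback_windows,
    simulate,
)
from ..track_stats import TrackSet
from .io import write_bulk, write_snapshot, write_tracks
from .manifest import RunManifest, write_manifest

__all__ = ["SCENARIOS", "scenario_config", "make_fixtures", "PERTURBATION_ONSET_H"]

PERTURBATION_ONSET_H = 24.0

SCENARIOS = (
    "null_timer",
    "sizer",
    "feedback_dips",
    "rapamycin_like",
    "sns_like",
    "perfect_compensation_panel",
)


def scenario_config(scenario: str, seed: int) -> SimConfig:
    """The SimConfig a scenario runs with (simulation scenarios only)."""
    if scenario == "null_timer":
        return SimConfig(g1_exit_rule="timer", seed=seed)
    if scenario == "sizer":
        return SimConfig(g1_exit_rule="sizer", seed=seed)
    if scenario == "feedback_dips":
        return SimConfig(
            g1_exit_rule="timer", feedback_windows=default_feedback_windows(), seed=seed
        )
    if scenario == "rapamycin_like":
        # growth inhibition against the G1 sizer alone: the drug's primary
        # effect on growth rate is then undiluted by fast growth feedback
        return SimConfig(
            g1_exit_rule="sizer",
            perturbation=Perturbation(PERTURBATION_ONSET_H, growth_scale=0.4),
            seed=seed,
        )
    if scenario == "sns_like":
        return SimConfig(
            g1_exit_rule="sizer",
            feedback_windows=default_feedback_windows(),
            perturbation=Perturbation(PERTURBATION_ONSET_H, cycle_scale=0.5),
            seed=seed,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def _perfect_panel() -> pd.DataFrame:
    """Bulk panel in the perfect-compensation limit, v_i = C / tau_i exactly."""
    taus = {"control": 21.0, "slowA": 28.0, "slowB": 36.0, "fastA": 16.0, "fastB": 12.0}
    sbar = 150.0
    t = np.arange(0.0, 72.1, 6.0)
    frames = []
    for cond, tau in taus.items():
        n = 200.0 * 2.0 ** (t / tau)  # exact real-valued counts
        frames.append(
            pd.DataFrame(
                {"condition": cond, "t_h": t, "n_cells": n, "mean_size_au": sbar}
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_fixtures(scenario: str, seed: int, out_dir: str | Path | None = None) -> dict:
    """Build a deterministic scenario dataset; optionally write it to disk.

    Returns a dict with the tables ('snapshot', 'tracks', 'bulk', 'config')
    present for the scenario.  With ``out_dir`` the tables are written in
    the canonical CSV dialect together with a run manifest.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")

    if scenario == "perfect_compensation_panel":
        data: dict = {"bulk": _perfect_panel(), "config": {"scenario": scenario}}
    else:
        config = scenario_config(scenario, seed)
        if scenario in ("rapamycin_like", "sns_like"):
            # control arm shares the seed; drug arm carries the perturbation
            control_cfg = SimConfig(
                **{**config.to_dict(), "perturbation": None}
            )
            drug = simulate(
                config, 96.0, 80, founder_stagger=21.0, record_tracks=False,
                condition=scenario,
            )
            ctrl = simulate(
                control_cfg, 96.0, 80, founder_stagger=21.0, record_tracks=False,
                condition="control",
            )
            data = {
                "snapshot": drug.snapshot,
                "bulk": pd.concat([ctrl.bulk, drug.bulk], ignore_index=True),
                "config": config.to_dict(),
            }
        else:
            res = simulate(config, 42.0, 400, founder_stagger=21.0)
            data = {
                "snapshot": res.snapshot,
                "tracks": TrackSet(res.track_samples, res.track_events),
                "bulk": res.bulk,
                "config": config.to_dict(),
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "snapshot" in data:
            write_snapshot(data["snapshot"], out / "snapshot.csv")
        if "tracks" in data:
            write_tracks(data["tracks"], out)
        if "bulk" in data:
            write_bulk(data["bulk"], out / "bulk.csv")
        cfg = data.get("config", {"scenario": scenario})
        write_manifest(RunManifest.create(cfg if isinstance(cfg, dict) else cfg, seed), out / "manifest.json")
    return data
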