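"""Shared table schemas, readers/writers and column mapping.

Canonical on-disk dialect: comma-separated, UTF-8, header row, '.' decimal.
Three table kinds:

* snapshot: cell_id, age_h, size_au, nucleus_au, phase
* track samples (long): cell_id, t_h, nucleus_au  (+ per-cell events table)
* bulk: condition, t_h, n_cells, mean_size_au

Deposited single-cell datasets often name columns after the assay
("cell age", "total SE-A647 intensity", "total mAG-hGem intensity",
"nucleus size"); a :class:`ColumnMapping` translates such vocabularies to
the canonical fields.  When a snapshot carries a post-G1 reporter
intensity instead of an explicit phase label, phases are called by a
two-class Otsu threshold on the log intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from ..track_stats import TrackSet

__all__ = [
    "ColumnMapping",
    "PAPER_SNAPSHOT_ALIASES",
    "SNAPSHOT_COLUMNS",
    "TRACK_SAMPLE_COLUMNS",
    "TRACK_EVENT_COLUMNS",
    "BULK_COLUMNS",
    "load_table",
    "classify_phase_from_marker",
    "write_snapshot",
    "write_tracks",
    "write_bulk",
    "read_tracks",
]

logger = logging.getLogger(__name__)

SNAPSHOT_COLUMNS = ["cell_id", "age_h", "size_au", "nucleus_au", "phase"]
TRACK_SAMPLE_COLUMNS = ["cell_id", "t_h", "nucleus_au"]
TRACK_EVENT_COLUMNS = [
    "cell_id",
    "parent_id",
    "birth_time_h",
    "birth_size_au",
    "g1_exit_time_h",
    "mitosis_onset_h",
    "division_time_h",
    "division_size_au",
]
BULK_COLUMNS = ["condition", "t_h", "n_cells", "mean_size_au"]

# common source-data vocabulary → canonical fields
PAPER_SNAPSHOT_ALIASES = {
    "cell age": "age_h",
    "cell age (hr)": "age_h",
    "total SE-A647 intensity": "size_au",
    "total mAG-hGem intensity": "phase_marker_au",
    "nucleus size": "nucleus_au",
}


@dataclass
class ColumnMapping:
    """Source column name → canonical field name."""

    mapping: dict[str, str] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        return df.rename(columns=self.mapping)


_REQUIRED = {
    "snapshot": ["age_h", "size_au"],
    "track": ["cell_id", "t_h", "nucleus_au"],
    "bulk": ["condition", "t_h", "n_cells", "mean_size_au"],
}


def classify_phase_from_marker(marker: np.ndarray) -> np.ndarray:
    """Two-class call of G1 vs post-G1 from a degron-reporter intensity.

    Threshold = Otsu on the log intensity; cells above it are labelled
    'postG1' (reporter accumulates after G1 exit), the rest 'G1'.
    """
    marker = np.asarray(marker, dtype=float)
    if np.any(marker <= 0):
        raise ValueError("marker intensities must be positive for log thresholding")
    thr = threshold_otsu(np.log(marker))
    return np.where(np.log(marker) > thr, "postG1", "G1").astype(object)


def load_table(
    path, kind: str, mapping: ColumnMapping | dict | None = None
) -> pd.DataFrame:
    """Read, map and validate a delimited table; invalid rows are dropped.

    Rows violating basic invariants (negative age, non-positive size or
    count, non-increasing phase vocabulary) are removed with a logged
    count.  Raises when required columns are missing or nothing survives
    validation.
    """
    if kind not in _REQUIRED:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    if mapping is not None:
        if isinstance(mapping, dict):
            mapping = ColumnMapping(mapping)
        df = mapping.apply(df)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if kind == "snapshot" and "phase" not in df.columns and "phase_marker_au" in df.columns:
        df = df.copy()
        df["phase"] = classify_phase_from_marker(df["phase_marker_au"].to_numpy())
    if missing:
        raise ValueError(f"missing required columns for {kind}: {missing}")

    n0 = len(df)
    if kind == "snapshot":
        ok = (df["age_h"] >= 0) & (df["size_au"] > 0)
        if "nucleus_au" in df.columns:
            ok &= df["nucleus_au"].isna() | (df["nucleus_au"] > 0)
        if "phase" in df.columns:
            ok &= df["phase"].isin(["G1", "postG1", "M"]) | df["phase"].isna()
        if "cell_id" not in df.columns:
            df = df.copy()
            df["cell_id"] = np.arange(len(df))
    elif kind == "track":
        ok = df["nucleus_au"] > 0
    else:
        ok = (df["n_cells"] >= 1) & (df["mean_size_au"] > 0)
    out = df.loc[ok].reset_index(drop=True)
    dropped = n0 - len(out)
    if dropped:
        logger.info("load_table(%s): dropped %d of %d rows failing validation", kind, dropped, n0)
    if out.empty:
        raise ValueError(f"no valid rows left in {path}")
    logger.info("load_table(%s): %d records", kind, len(out))
    return out


def write_snapshot(snapshot: pd.DataFrame, path) -> Path:
    path = Path(path)
    snapshot.to_csv(path, index=False, columns=SNAPSHOT_COLUMNS)
    return path


def write_tracks(tracks: TrackSet, directory) -> tuple[Path, Path]:
    """Write long-format samples plus the per-cell events table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp = directory / "track_samples.csv"
    ep = directory / "track_events.csv"
    tracks.samples.to_csv(sp, index=False, columns=TRACK_SAMPLE_COLUMNS)
    cols = [c for c in TRACK_EVENT_COLUMNS if c in tracks.events.columns]
    tracks.events.to_csv(ep, index=False, columns=cols)
    return sp, ep


def read_tracks(directory) -> TrackSet:
    directory = Path(directory)
    samples = load_table(directory / "track_samples.csv", "track")
    events = pd.read_csv(directory / "track_events.csv")
    return TrackSet(samples, events)


def write_bulk(bulk: pd.DataFrame, path) -> Path:
    path = Path(path)
    bulk.to_csv(path, index=False, columns=BULK_COLUMNS)
    return path
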