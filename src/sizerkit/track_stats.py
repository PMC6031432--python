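"""Time-lapse track analysis: G1 length, birth-size coupling, growth correlations.

Tracks are nucleus-proxy time series sampled on a fixed interval, paired
with a per-cell events table (birth, G1 exit, mitosis onset, division).
Following standard practice for nuclear-area proxies, the first 1.25 h of
every trajectory is trimmed (the nucleus flattens after mitosis) and
trajectories end at mitosis onset (nuclear-envelope breakdown), so "size
at birth" is operationalized as the first retained sample, ~1.25 h after
birth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrackSet",
    "CorrelationReport",
    "AgeResolvedCorrelation",
    "DecileConvergence",
    "preprocess_track",
    "preprocess_tracks",
    "g1_duration",
    "birth_size_g1_correlation",
    "growth_vs_size_by_age",
    "extreme_decile_convergence",
]

logger = logging.getLogger(__name__)

DEFAULT_TRIM_H = 1.25
_EPS = 1e-9


@dataclass
class TrackSet:
    """Long-format samples (cell_id, t_h, nucleus_au) plus per-cell events."""

    samples: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("cell_id", "t_h", "nucleus_au"):
            if col not in self.samples.columns:
                raise ValueError(f"samples missing column {col!r}")
        for col in ("cell_id", "birth_time_h"):
            if col not in self.events.columns:
                raise ValueError(f"events missing column {col!r}")

    @property
    def sampling_interval(self) -> float:
        t = np.sort(self.samples["t_h"].unique())
        if len(t) < 2:
            raise ValueError("cannot infer sampling interval from < 2 sample times")
        return float(np.min(np.diff(t)))

    def events_indexed(self) -> pd.DataFrame:
        return self.events.set_index("cell_id")


def _end_time(ev_row) -> float:
    """Trajectory end: mitosis onset if known, else division time, else +inf."""
    for col in ("mitosis_onset_h", "division_time_h"):
        v = ev_row.get(col, np.nan)
        if v is not None and np.isfinite(v):
            return float(v)
    return np.inf


def preprocess_track(
    samples: pd.DataFrame, birth_time: float, end_time: float = np.inf, trim: float = DEFAULT_TRIM_H
) -> pd.DataFrame:
    """Trim one track: drop samples younger than ``trim`` and at/after mitosis.

    Raises ValueError when fewer than 3 samples survive.
    """
    t = np.asarray(samples["t_h"], dtype=float)
    keep = (t - birth_time >= trim - _EPS) & (t < end_time - _EPS)
    out = samples.loc[keep]
    if len(out) < 3:
        raise ValueError("track too short after trimming")
    return out


def preprocess_tracks(tracks: TrackSet, trim: float = DEFAULT_TRIM_H) -> TrackSet:
    """Trim all tracks; tracks left with < 3 samples are dropped and logged."""
    ev = tracks.events_indexed()
    born = ev["birth_time_h"]
    s = tracks.samples
    cid = s["cell_id"].to_numpy()
    t = s["t_h"].to_numpy(dtype=float)
    birth = born.reindex(cid).to_numpy(dtype=float)
    end = np.full(len(cid), np.inf)
    for col in ("division_time_h", "mitosis_onset_h"):
        if col in ev.columns:
            v = ev[col].reindex(cid).to_numpy(dtype=float)
            end = np.where(np.isfinite(v), v, end)
    keep = (t - birth >= trim - _EPS) & (t < end - _EPS)
    kept = s.loc[keep]
    counts = kept.groupby("cell_id").size()
    good = counts[counts >= 3].index
    n_dropped = ev.index.nunique() - len(good)
    if n_dropped:
        logger.info("preprocess_tracks: dropped %d tracks with < 3 retained samples", n_dropped)
    kept = kept[kept["cell_id"].isin(good)]
    return TrackSet(kept.reset_index(drop=True), tracks.events)


def g1_duration(events: pd.DataFrame) -> pd.Series:
    """G1 length per cell: g1_exit_time - birth_time (hours).

    Cells without an observed G1 exit are omitted; a negative duration is
    an invariant violation and raises.
    """
    ev = events.dropna(subset=["g1_exit_time_h"])
    dur = ev["g1_exit_time_h"] - ev["birth_time_h"]
    if (dur < -_EPS).any():
        raise ValueError("g1_exit_time precedes birth_time")
    return pd.Series(dur.to_numpy(), index=ev["cell_id"].to_numpy(), name="g1_duration_h")


@dataclass
class CorrelationReport:
    """Pearson correlation with analytic and permutation-based inference."""

    r: float
    p_value: float  # Student-t transform of r, two-sided
    n: int
    null_distribution: np.ndarray = field(repr=False)
    permutation_p: float
    slope: float  # regression of G1 length on birth size
    intercept: float


def _first_retained_sample(tracks: TrackSet, trim: float):
    """Per cell: nucleus value at the first sample >= trim hours after birth."""
    ev = tracks.events_indexed()
    s = tracks.samples
    birth = ev["birth_time_h"].reindex(s["cell_id"]).to_numpy(dtype=float)
    age = s["t_h"].to_numpy(dtype=float) - birth
    ok = s.loc[age >= trim - _EPS, ["cell_id", "t_h", "nucleus_au"]]
    first = ok.sort_values(["cell_id", "t_h"]).groupby("cell_id").first()
    return first  # index cell_id, columns t_h, nucleus_au


def birth_size_g1_correlation(
    tracks: TrackSet,
    n_perm: int = 1000,
    seed: int = 0,
    trim: float = DEFAULT_TRIM_H,
) -> CorrelationReport:
    """Correlate nucleus size ~``trim`` h after birth with G1 duration.

    Cells whose G1 exit (or division) precedes the first retained sample
    are excluded.  The permutation null shuffles G1 durations against the
    size values; the reported permutation p is the fraction of |null r|
    >= |observed r| (add-one convention).
    """
    first = _first_retained_sample(tracks, trim)
    dur = g1_duration(tracks.events)
    common = first.index.intersection(dur.index)
    # exclude cells that left G1 before the first retained sample
    exit_t = tracks.events_indexed()["g1_exit_time_h"].reindex(common)
    common = common[first.loc[common, "t_h"].to_numpy() < exit_t.to_numpy() + _EPS]
    if len(common) < 20:
        raise ValueError("fewer than 20 usable tracks")
    x = first.loc[common, "nucleus_au"].to_numpy(dtype=float)
    y = dur.loc[common].to_numpy(dtype=float)

    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E12]))
    xc = (x - x.mean()) / (x.std() * len(x))
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        null_r = (pc @ xc) / y.std()
    perm_p = (1.0 + np.sum(np.abs(null_r) >= abs(r))) / (n_perm + 1.0)

    return CorrelationReport(
        r=float(r),
        p_value=float(p),
        n=len(x),
        null_distribution=null_r,
        permutation_p=float(perm_p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


@dataclass
class AgeResolvedCorrelation:
    """r(size at age a, growth over the next ``lag`` hours) versus age."""

    age_grid: np.ndarray
    r_values: np.ndarray  # NaN where undefined
    n_per_age: np.ndarray
    defined: np.ndarray
    lag: float


def _age_matrix(tracks: TrackSet, dt: float):
    """(cells x age-index) matrix of nucleus values on the sampling grid."""
    ev = tracks.events_indexed()
    s = tracks.samples
    birth = ev["birth_time_h"].reindex(s["cell_id"]).to_numpy(dtype=float)
    aidx = np.rint((s["t_h"].to_numpy(dtype=float) - birth) / dt).astype(int)
    ok = aidx >= 0
    df = pd.DataFrame(
        {
            "cell_id": s["cell_id"].to_numpy()[ok],
            "aidx": aidx[ok],
            "nuc": s["nucleus_au"].to_numpy(dtype=float)[ok],
        }
    )
    mat = df.pivot_table(index="cell_id", columns="aidx", values="nuc", aggfunc="first")
    mat = mat.sort_index()
    return mat


def growth_vs_size_by_age(
    tracks: TrackSet,
    lag: float = 2.5,
    min_n: int = 20,
    dt: float | None = None,
) -> AgeResolvedCorrelation:
    """Pearson r between nucleus size and its subsequent lagged increment, by age.

    For each age a on the sampling grid, over cells sampled at both a and
    a + lag: r( N(a), N(a+lag) - N(a) ).  Ages with fewer than ``min_n``
    cells, or with degenerate (zero-variance) inputs, are flagged
    undefined (NaN), not zero-filled.
    """
    if dt is None:
        dt = tracks.sampling_interval
    k = round(lag / dt)
    if abs(k * dt - lag) > 1e-9 or k < 1:
        raise ValueError("lag must be a positive multiple of the sampling interval")
    mat = _age_matrix(tracks, dt)
    ncol = mat.shape[1]
    ages, rs, ns = [], [], []
    vals = mat.to_numpy()
    cols = mat.columns.to_numpy()
    colpos = {c: i for i, c in enumerate(cols)}
    for c in cols:
        if c + k not in colpos:
            continue
        x = vals[:, colpos[c]]
        x2 = vals[:, colpos[c + k]]
        ok = np.isfinite(x) & np.isfinite(x2)
        n = int(ok.sum())
        ages.append(c * dt)
        ns.append(n)
        if n < min_n:
            rs.append(np.nan)
            continue
        xv = x[ok]
        dv = x2[ok] - xv
        if xv.std() == 0 or dv.std() == 0:
            rs.append(np.nan)
            continue
        rs.append(stats.pearsonr(xv, dv)[0])
    r_values = np.asarray(rs, dtype=float)
    return AgeResolvedCorrelation(
        age_grid=np.asarray(ages, dtype=float),
        r_values=r_values,
        n_per_age=np.asarray(ns, dtype=int),
        defined=np.isfinite(r_values),
        lag=lag,
    )


@dataclass
class DecileConvergence:
    """Mean trajectories of the extreme groups and their gap ratio."""

    age_grid: np.ndarray
    mean_large: np.ndarray
    mean_small: np.ndarray
    gap_ratio: float
    sort_age: float
    reference_age: float
    large_ids: np.ndarray
    small_ids: np.ndarray


def extreme_decile_convergence(
    tracks: TrackSet,
    sort_age: float = 10.0,
    k: int = 10,
    reference_age: float | None = None,
    dt: float | None = None,
) -> DecileConvergence:
    """Compare growth of the k largest vs k smallest cells at ``sort_age``.

    gap_ratio = (large mean - small mean at the reference age) /
    (same gap at the sort age); < 1 indicates convergence (feedback), > 1
    divergence (e.g. exponential growth).  The reference age defaults to
    the last age at which >= 2k of the eligible tracks are still sampled.
    Ties in the ranking are broken by cell id for determinism.
    """
    if dt is None:
        dt = tracks.sampling_interval
    mat = _age_matrix(tracks, dt)
    js = round(sort_age / dt)
    if js not in mat.columns:
        raise ValueError(f"no samples at sort_age={sort_age}")
    vals = mat.to_numpy()
    cols = mat.columns.to_numpy()
    jcol = int(np.flatnonzero(cols == js)[0])
    at_sort = np.isfinite(vals[:, jcol])

    if reference_age is None:
        later = [
            i
            for i in range(jcol + 1, len(cols))
            if (at_sort & np.isfinite(vals[:, i])).sum() >= 2 * k
        ]
        if not later:
            raise ValueError("no later age with >= 2k eligible tracks")
        jref = later[-1]
    else:
        jr = round(reference_age / dt)
        if jr not in cols:
            raise ValueError(f"no samples at reference_age={reference_age}")
        jref = int(np.flatnonzero(cols == jr)[0])

    eligible = at_sort & np.isfinite(vals[:, jref])
    if eligible.sum() < 2 * k:
        raise ValueError("fewer than 2k eligible tracks")
    idx = np.flatnonzero(eligible)
    order = idx[np.argsort(vals[idx, jcol], kind="stable")]  # ties: cell-id order
    small = order[:k]
    large = order[-k:]

    gap_sort = vals[large, jcol].mean() - vals[small, jcol].mean()
    gap_ref = vals[large, jref].mean() - vals[small, jref].mean()
    if gap_sort == 0:
        raise ValueError("zero size gap at sort age")

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_large = np.nanmean(vals[large, :], axis=0)
        mean_small = np.nanmean(vals[small, :], axis=0)
    ids = mat.index.to_numpy()
    return DecileConvergence(
        age_grid=cols * dt,
        mean_large=mean_large,
        mean_small=mean_small,
        gap_ratio=float(gap_ref / gap_sort),
        sort_age=js * dt,
        reference_age=float(cols[jref] * dt),
        large_ids=ids[large],
        small_ids=ids[small],
    )
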