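"""Fixed-population (snapshot) analysis of cell size versus cell age.

The central quantity is the signed *coefficient of growth-rate variation*

    G_cv(a) = +sqrt(dVar) / dMean   if dVar > 0
              -sqrt(|dVar|) / dMean if dVar < 0
              0                     if dVar = 0

where dVar = Var(S)(a + lag) - Var(S)(a) and dMean = mean(S)(a + lag) -
mean(S)(a) are lagged differences of the age-resolved variance and mean of
cell size.  The logic rests on the exact decomposition

    Var(S2) = Var(S1) + Var(dS) + 2 Cov(S1, dS)

for cells growing from S1 to S2 = S1 + dS: variance can *decrease* while
cells grow only if size and subsequent growth are negatively correlated.
When growth is size-independent, G_cv equals the coefficient of variation
of the growth increments, sigma_gr / mu_gr (and equals 1 when growth is a
unit-rate Poisson process).

Mean and variance curves are estimated by Gaussian-kernel local-linear
regression; the variance function uses the standard two-stage estimator
(local-linear regression of squared residuals around the fitted mean).
Confidence bands come from a cell-level bootstrap; G_cv bands use a
*joint* bootstrap in which each resample re-fits both curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeCurve",
    "GcvCurve",
    "CheckpointResult",
    "mean_size_vs_age",
    "var_size_vs_age",
    "gcv_vs_age",
    "gcv_analysis",
    "gcv_paired",
    "variance_decomposition",
    "checkpoint_contrast",
    "doubling_ratio",
    "size_variability",
]

_EPS = 1e-12


@dataclass
class AgeCurve:
    """An age-resolved estimate (mean or variance of size) with bootstrap CI."""

    age_grid: np.ndarray
    estimate: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_eff: np.ndarray
    kind: str  # "mean" | "variance"
    bandwidth: float
    boot: np.ndarray | None = field(default=None, repr=False)  # (n_boot, n_grid)
    boot_seed: int | None = None

    @property
    def spacing(self) -> float:
        return float(self.age_grid[1] - self.age_grid[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_h": self.age_grid,
                "estimate": self.estimate,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n_eff": self.n_eff,
            }
        )


@dataclass
class GcvCurve:
    """Lagged variance/mean differences and the signed G_cv statistic."""

    age_grid: np.ndarray
    delta_var: np.ndarray
    delta_mean: np.ndarray
    gcv: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    lag: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_h": self.age_grid,
                "delta_var": self.delta_var,
                "delta_mean": self.delta_mean,
                "gcv": self.gcv,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


@dataclass
class CheckpointResult:
    """Age-matched G1 vs post-G1 size contrast."""

    age_bins: np.ndarray  # bin centers of qualifying bins
    mean_g1: np.ndarray
    mean_postg1: np.ndarray
    bin_n_g1: np.ndarray
    bin_n_postg1: np.ndarray
    t_statistic: float
    p_value: float
    plateau_flag: bool
    plateau_slope: float
    plateau_slope_se: float


# ---------------------------------------------------------------------------
# local-linear kernel machinery

class _LocalLinear:
    """Precomputed Gaussian-kernel design for fast reweighted (bootstrap) fits.

    A cell-level bootstrap resample is equivalent to reweighting each
    observation by its multinomial count, so one precomputed kernel matrix
    serves the base fit and every bootstrap replicate.
    """

    def __init__(self, x: np.ndarray, grid: np.ndarray, bandwidth: float):
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        self.x = x
        self.grid = grid
        d = (grid[:, None] - x[None, :]) / bandwidth
        self.K = np.exp(-0.5 * d * d)
        self.D = grid[:, None] - x[None, :]
        mass = self.K.sum(axis=1)
        if np.any(mass < 1e-12):
            raise ValueError(
                "bandwidth too small: a grid point has zero kernel mass"
            )
        self.KD = self.K * self.D
        self.KD2 = self.KD * self.D

    def n_eff(self) -> np.ndarray:
        s = self.K.sum(axis=1)
        return s * s / (self.K * self.K).sum(axis=1)

    def fit(self, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
        """Local-linear estimate on the grid with optional case weights ``w``."""
        if w is None:
            s0 = self.K.sum(axis=1)
            s1 = self.KD.sum(axis=1)
            s2 = self.KD2.sum(axis=1)
            b0 = self.K @ y
            b1 = self.KD @ y
        else:
            s0 = self.K @ w
            s1 = self.KD @ w
            s2 = self.KD2 @ w
            wy = w * y
            b0 = self.K @ wy
            b1 = self.KD @ wy
        den = s0 * s2 - s1 * s1
        # guard: if the weighted x-values are (numerically) identical around a
        # grid point, local-linear is singular; fall back to the local mean.
        scale = np.maximum(s0 * s2, s0 * s0 * 1e-30) + 1e-300
        singular = den <= 1e-10 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            est = (s2 * b0 - s1 * b1) / den
            nw = b0 / np.where(s0 > 0, s0, np.nan)
        est = np.where(singular, nw, est)
        return est


def _boot_counts(n: int, n_boot: int, seed: int) -> np.ndarray:
    """Multinomial bootstrap count matrix (n_boot, n), deterministic in seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    idx = rng.integers(0, n, size=(n_boot, n))
    counts = np.zeros((n_boot, n))
    rows = np.repeat(np.arange(n_boot), n)
    np.add.at(counts, (rows, idx.ravel()), 1.0)
    return counts


def _default_grid(age: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    hi = np.floor(age.max() / spacing) * spacing
    return np.arange(0.0, hi + spacing / 2, spacing)


def _extract(snapshot, value_col: str = "size_au"):
    age = np.asarray(snapshot["age_h"], dtype=float)
    y = np.asarray(snapshot[value_col], dtype=float)
    return age, y


def _curve_pair_core(
    age: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
    counts: np.ndarray | None,
):
    """Mean curve and two-stage variance curve for one (re)weighting."""
    ll = _LocalLinear(age, grid, bandwidth)
    # residuals need the mean fit across the full data range, not just the
    # analysis grid, so extend the interpolation grid to cover all ages
    spacing = grid[1] - grid[0] if len(grid) > 1 else bandwidth
    lo = min(grid[0], np.floor(age.min() / spacing) * spacing)
    hi = max(grid[-1], np.ceil(age.max() / spacing) * spacing)
    full_grid = np.arange(lo, hi + spacing / 2, spacing)
    ll_full = _LocalLinear(age, full_grid, bandwidth)

    def one(w):
        m = ll.fit(y, w)
        fitted_at_x = np.interp(age, full_grid, ll_full.fit(y, w))
        resid2 = (y - fitted_at_x) ** 2
        v = ll.fit(resid2, w)
        return m, v

    m0, v0 = one(None)
    if counts is None:
        return ll, m0, v0, None, None
    mb = np.empty((len(counts), len(grid)))
    vb = np.empty_like(mb)
    for i, w in enumerate(counts):
        mb[i], vb[i] = one(w)
    return ll, m0, v0, mb, vb


def _percentile_ci(boot: np.ndarray, ci_level: float):
    alpha = (1.0 - ci_level) / 2.0
    lo = np.nanquantile(boot, alpha, axis=0)
    hi = np.nanquantile(boot, 1.0 - alpha, axis=0)
    return lo, hi


def _mask_low_n(curve_vals, n_eff, min_n_eff):
    bad = n_eff < min_n_eff
    out = []
    for v in curve_vals:
        v = v.copy()
        v[bad] = np.nan
        out.append(v)
    return out


def _make_curves(
    snapshot,
    bandwidth: float,
    n_boot: int,
    ci_mean: float,
    ci_var: float,
    grid: np.ndarray | None,
    seed: int,
    min_n_eff: float,
    value_col: str,
):
    age, y = _extract(snapshot, value_col)
    if len(age) < 50:
        raise ValueError("snapshot must contain at least 50 cells")
    if grid is None:
        grid = _default_grid(age)
    counts = _boot_counts(len(age), n_boot, seed) if n_boot > 0 else None
    ll, m0, v0, mb, vb = _curve_pair_core(age, y, grid, bandwidth, counts)
    n_eff = ll.n_eff()

    neg = v0 < 0
    if np.any(neg):
        warnings.warn(
            f"variance estimate negative at {int(neg.sum())} grid points; clipped to 0",
            stacklevel=2,
        )
    v0c = np.clip(v0, 0.0, None)

    if mb is not None:
        m_lo, m_hi = _percentile_ci(mb, ci_mean)
        v_lo, v_hi = _percentile_ci(np.clip(vb, 0.0, None), ci_var)
    else:
        m_lo = m_hi = np.full_like(m0, np.nan)
        v_lo = v_hi = np.full_like(v0, np.nan)

    m0m, m_lo, m_hi = _mask_low_n((m0, m_lo, m_hi), n_eff, min_n_eff)
    v0m, v_lo, v_hi = _mask_low_n((v0c, v_lo, v_hi), n_eff, min_n_eff)

    mean_curve = AgeCurve(grid, m0m, m_lo, m_hi, n_eff, "mean", bandwidth, mb, seed)
    var_curve = AgeCurve(grid, v0m, v_lo, v_hi, n_eff, "variance", bandwidth, vb, seed)
    return mean_curve, var_curve


def mean_size_vs_age(
    snapshot,
    bandwidth: float = 1.0,
    n_boot: int = 200,
    ci_level: float = 0.90,
    *,
    grid: np.ndarray | None = None,
    seed: int = 0,
    min_n_eff: float = 25.0,
    value_col: str = "size_au",
) -> AgeCurve:
    """Local-linear regression of size on age with bootstrap percentile CI.

    The 90% default CI level matches common practice for mean-size curves.
    Grid points whose effective kernel sample size falls below
    ``min_n_eff`` are reported as NaN rather than extrapolated.
    """
    mean_curve, _ = _make_curves(
        snapshot, bandwidth, n_boot, ci_level, 0.70, grid, seed, min_n_eff, value_col
    )
    return mean_curve


def var_size_vs_age(
    snapshot,
    bandwidth: float = 1.0,
    n_boot: int = 200,
    ci_level: float = 0.70,
    *,
    grid: np.ndarray | None = None,
    seed: int = 0,
    min_n_eff: float = 25.0,
    value_col: str = "size_au",
) -> AgeCurve:
    """Two-stage variance-function estimate (population-variance convention).

    Squared residuals around the fitted mean curve are themselves smoothed
    by local-linear regression.  Negative point estimates are clipped to 0
    with a warning.  Default CI level 0.70.
    """
    _, var_curve = _make_curves(
        snapshot, bandwidth, n_boot, 0.90, ci_level, grid, seed, min_n_eff, value_col
    )
    return var_curve


def _gcv_transform(dvar: np.ndarray, dmean: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.sign(dvar) * np.sqrt(np.abs(dvar)) / dmean
    g = np.where(dvar == 0, 0.0, g)
    g = np.where(dmean > 0, g, np.nan)  # evaluation suppressed where dMean <= 0
    return g


def gcv_vs_age(
    mean_curve: AgeCurve,
    var_curve: AgeCurve,
    lag: float = 2.5,
    ci_level: float = 0.50,
) -> GcvCurve:
    """Signed G_cv over a lagged age difference, with joint-bootstrap CI.

    Both curves must share the same grid and carry bootstrap replicates
    produced from the same cell-level resamples (use :func:`gcv_analysis`,
    or call the two curve estimators with identical snapshot/seed/n_boot).
    The default 50% band follows common usage for this statistic.
    """
    if lag <= 0:
        raise ValueError("lag must be > 0")
    if not np.array_equal(mean_curve.age_grid, var_curve.age_grid):
        raise ValueError("mean and variance curves must share a grid")
    spacing = mean_curve.spacing
    k = round(lag / spacing)
    if abs(k * spacing - lag) > 1e-9 or k < 1:
        raise ValueError("lag must be a positive multiple of the grid spacing")

    grid = mean_curve.age_grid[:-k]
    m, v = mean_curve.estimate, var_curve.estimate
    dvar = v[k:] - v[:-k]
    dmean = m[k:] - m[:-k]
    gcv = _gcv_transform(dvar, dmean)

    if mean_curve.boot is not None and var_curve.boot is not None:
        if (
            mean_curve.boot.shape != var_curve.boot.shape
            or mean_curve.boot_seed != var_curve.boot_seed
        ):
            raise ValueError("curves carry incompatible bootstrap replicates")
        mb, vb = mean_curve.boot, np.clip(var_curve.boot, 0.0, None)
        gb = _gcv_transform(vb[:, k:] - vb[:, :-k], mb[:, k:] - mb[:, :-k])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ci_lo, ci_hi = _percentile_ci(gb, ci_level)
    else:
        ci_lo = ci_hi = np.full_like(gcv, np.nan)
    bad = np.isnan(gcv)
    ci_lo = np.where(bad, np.nan, ci_lo)
    ci_hi = np.where(bad, np.nan, ci_hi)
    return GcvCurve(grid, dvar, dmean, gcv, ci_lo, ci_hi, lag)


def gcv_analysis(
    snapshot,
    bandwidth: float = 1.0,
    lag: float = 2.5,
    n_boot: int = 200,
    ci_mean: float = 0.90,
    ci_var: float = 0.70,
    ci_gcv: float = 0.50,
    *,
    grid: np.ndarray | None = None,
    seed: int = 0,
    min_n_eff: float = 25.0,
    value_col: str = "size_au",
) -> tuple[AgeCurve, AgeCurve, GcvCurve]:
    """Mean curve, variance curve and G_cv with a shared joint bootstrap."""
    mean_curve, var_curve = _make_curves(
        snapshot, bandwidth, n_boot, ci_mean, ci_var, grid, seed, min_n_eff, value_col
    )
    return mean_curve, var_curve, gcv_vs_age(mean_curve, var_curve, lag, ci_gcv)


# ---------------------------------------------------------------------------
# paired-cohort diagnostics (exact, no smoothing)

def variance_decomposition(s1, s2) -> dict:
    """Exact decomposition Var(S2) = Var(S1) + Var(dS) + 2 Cov(S1, dS).

    Population-variance convention (ddof=0).  ``residual`` is the identity
    defect and is zero up to floating-point error for any paired data.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1 or len(s1) < 2:
        raise ValueError("s1 and s2 must be equal-length 1-d arrays, n >= 2")
    ds = s2 - s1
    var1 = float(np.var(s1))
    var2 = float(np.var(s2))
    var_ds = float(np.var(ds))
    cov = float(np.mean((s1 - s1.mean()) * (ds - ds.mean())))
    return {
        "var_s1": var1,
        "var_s2": var2,
        "var_ds": var_ds,
        "cov_s1_ds": cov,
        "delta_var": var2 - var1,
        "residual": var2 - var1 - var_ds - 2.0 * cov,
    }


def gcv_paired(s1, s2) -> float:
    """G_cv between two size vectors of the same cohort (start/end of interval)."""
    d = variance_decomposition(s1, s2)
    dmean = float(np.mean(np.asarray(s2, float)) - np.mean(np.asarray(s1, float)))
    if dmean <= 0:
        raise ValueError("mean size must increase over the interval")
    dvar = d["delta_var"]
    if dvar == 0:
        return 0.0
    return float(np.sign(dvar) * np.sqrt(abs(dvar)) / dmean)


# ---------------------------------------------------------------------------
# checkpoint contrast, doubling check, robust variability

def checkpoint_contrast(
    snapshot,
    age_bin_width: float = 1.5,
    min_bin_n: int = 10,
    *,
    g1_label: str = "G1",
    postg1_labels: tuple[str, ...] = ("postG1", "M"),
    n_plateau_bins: int = 3,
) -> CheckpointResult:
    """Age-matched contrast of post-G1 vs G1 mean size.

    Cells are binned by age; within qualifying bins (>= ``min_bin_n`` cells
    of each class) sizes are detrended by the bin-wise all-cell mean, then
    pooled into a Welch two-sample t-test (post-G1 minus G1).  The plateau
    flag reports whether the G1 mean-size trend over the last qualifying
    bins is consistent with zero or negative slope (one-sided 95%), the
    signature of a size threshold gating G1 exit.
    """
    age = np.asarray(snapshot["age_h"], dtype=float)
    size = np.asarray(snapshot["size_au"], dtype=float)
    phase = np.asarray(snapshot["phase"], dtype=object)
    is_g1 = phase == g1_label
    is_pg1 = np.isin(phase, postg1_labels)
    if not is_g1.any() or not is_pg1.any():
        raise ValueError("snapshot must contain both G1 and post-G1 cells")

    nbins = int(np.ceil((age.max() + _EPS) / age_bin_width))
    which = np.minimum((age / age_bin_width).astype(int), nbins - 1)

    centers, mg1, mpg1, ng1, npg1 = [], [], [], [], []
    det_g1, det_pg1 = [], []
    g1_ages, g1_sizes = [], []
    for b in range(nbins):
        in_bin = which == b
        bg1 = in_bin & is_g1
        bpg1 = in_bin & is_pg1
        if bg1.sum() < min_bin_n or bpg1.sum() < min_bin_n:
            continue
        allmean = size[in_bin].mean()
        centers.append((b + 0.5) * age_bin_width)
        mg1.append(size[bg1].mean())
        mpg1.append(size[bpg1].mean())
        ng1.append(int(bg1.sum()))
        npg1.append(int(bpg1.sum()))
        det_g1.append(size[bg1] - allmean)
        det_pg1.append(size[bpg1] - allmean)
        g1_ages.append(age[bg1])
        g1_sizes.append(size[bg1])
    if len(centers) < 2:
        raise ValueError("fewer than 2 qualifying age bins")

    tstat, pval = stats.ttest_ind(
        np.concatenate(det_pg1), np.concatenate(det_g1), equal_var=False
    )

    # plateau: per-cell regression of G1 size on age over the last qualifying
    # bins.  The curve counts as plateaued when that slope is consistent with
    # zero (one-sided 95%) or has bent to less than half the early-age G1
    # slope — a size threshold compresses the late G1 pool against a ceiling,
    # so its mean flattens relative to the unconstrained early rise.
    kb = min(n_plateau_bins, len(centers))
    ga = np.concatenate(g1_ages[-kb:])
    gs = np.concatenate(g1_sizes[-kb:])
    fit = stats.linregress(ga, gs)
    fit_early = stats.linregress(
        np.concatenate(g1_ages[:kb]), np.concatenate(g1_sizes[:kb])
    )
    plateau = bool(
        fit.slope <= 2.0 * fit.stderr or fit.slope <= 0.5 * fit_early.slope
    )

    return CheckpointResult(
        age_bins=np.asarray(centers),
        mean_g1=np.asarray(mg1),
        mean_postg1=np.asarray(mpg1),
        bin_n_g1=np.asarray(ng1),
        bin_n_postg1=np.asarray(npg1),
        t_statistic=float(tstat),
        p_value=float(pval),
        plateau_flag=plateau,
        plateau_slope=float(fit.slope),
        plateau_slope_se=float(fit.stderr),
    )


def doubling_ratio(
    snapshot, newborn_window: float = 1.5, mitotic_phase: str = "M"
) -> float:
    """Mean size of mitotic cells over mean size of newborns (age <= window).

    At balanced growth this ratio is ~2: cells double over one cycle.
    """
    age = np.asarray(snapshot["age_h"], dtype=float)
    size = np.asarray(snapshot["size_au"], dtype=float)
    phase = np.asarray(snapshot["phase"], dtype=object)
    newborn = age <= newborn_window
    mitotic = phase == mitotic_phase
    if not newborn.any() or not mitotic.any():
        raise ValueError("newborn or mitotic group is empty")
    return float(size[mitotic].mean() / size[newborn].mean())


def size_variability(sizes) -> float:
    """Normalized median absolute deviation, MAD(x)/median(x).

    Robust dimensionless dispersion (no consistency constant), invariant
    to rescaling of the size unit.
    """
    x = np.asarray(sizes, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    if med <= 0:
        raise ValueError("median must be positive")
    return float(np.median(np.abs(x - med)) / med)
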