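"""Population-level compensation analysis.

From time courses of cell count N_t and mean cell size S̄_t, this module
estimates, per experimental condition:

* mean cell-cycle length τ, from an exponential fit N_t = N₀ e^{α t}
  with α = ln2/τ (least squares on ln N);
* mean single-cell growth rate v = (1/N_t) dM_t/dt, where M_t = N_t·S̄_t
  is the population's bulk mass — implemented as an exponential fit of
  M_t within the analysis window, evaluated at the window midpoint;
* the target size C_TS = v·τ, the product a homeostatic population
  defends: at balanced growth v·τ = ln2·S̄.

Drug-like time courses are split into an *early* stage (drug addition →
size stabilization) and a *late* stage (stabilized), each fitted
independently; the break is found by a piecewise (linear → constant)
least-squares search with a fixed 24 h fallback for flat series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitDiagnostics",
    "StageBreak",
    "CompensationEstimate",
    "ConditionPanel",
    "fit_cycle_length",
    "growth_rate_bulk",
    "segment_stages",
    "stagewise_estimates",
    "single_stage_estimate",
    "target_size_panel",
]

LN2 = math.log(2.0)
_EPS = 1e-12


@dataclass
class FitDiagnostics:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    tau_infinite: bool = False


def _series_arrays(series: pd.DataFrame):
    t = np.asarray(series["t_h"], dtype=float)
    n = np.asarray(series["n_cells"], dtype=float)
    s = np.asarray(series["mean_size_au"], dtype=float)
    order = np.argsort(t, kind="stable")
    return t[order], n[order], s[order]


def fit_cycle_length(times, counts) -> tuple[float, float, FitDiagnostics]:
    """Exponential proliferation fit: returns (alpha per hour, tau hours, diagnostics).

    alpha is the slope of ln N_t on t; tau = ln2/alpha.  A non-positive
    slope (non-proliferating/arrested condition) yields tau = +inf with a
    flag instead of an error, so such conditions survive panel assembly.
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(n < 1):
        raise ValueError("cell counts must be >= 1")
    fit = stats.linregress(t, np.log(n))
    alpha = float(fit.slope)
    diags = FitDiagnostics(
        slope=alpha,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(t),
        tau_infinite=alpha <= _EPS,
    )
    tau = math.inf if diags.tau_infinite else LN2 / alpha
    return alpha, tau, diags


def growth_rate_bulk(
    series: pd.DataFrame,
    window: tuple[float, float] | None = None,
    method: str = "exponential",
) -> float:
    """Average single-cell growth rate v = (1/N) dM/dt over a window.

    ``exponential`` (default): ln M is regressed on t within the window,
    giving rate alpha_M; v is evaluated at the window midpoint t* as
    alpha_M · M(t*) / N(t*), with M from the fit and N interpolated
    geometrically (linear in ln N, exact for exponential counts).

    ``difference``: mean of pointwise (ΔM/Δt) / N at interval midpoints,
    for comparison.
    """
    t, n, s = _series_arrays(series)
    m = n * s  # bulk mass, exactly N_t * S̄_t
    if np.any(m <= 0):
        raise ValueError("bulk mass must be positive")
    if window is None:
        window = (t[0], t[-1])
    lo, hi = window
    sel = (t >= lo - _EPS) & (t <= hi + _EPS)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points in the window")
    tw, nw, mw = t[sel], n[sel], m[sel]

    if method == "difference":
        dm = np.diff(mw) / np.diff(tw)
        nmid = np.exp((np.log(nw[1:]) + np.log(nw[:-1])) / 2.0)
        return float(np.mean(dm / nmid))
    if method != "exponential":
        raise ValueError(f"unknown method {method!r}")

    fit = stats.linregress(tw, np.log(mw))
    tstar = 0.5 * (tw[0] + tw[-1])
    m_star = math.exp(fit.intercept + fit.slope * tstar)
    n_star = math.exp(float(np.interp(tstar, tw, np.log(nw))))
    return float(fit.slope * m_star / n_star)


@dataclass
class StageBreak:
    time: float
    flagged: bool  # True when the search was degenerate and the fallback was used
    sse: float
    note: str = ""


def segment_stages(
    series: pd.DataFrame,
    fallback: float = 24.0,
    min_points: int = 3,
) -> StageBreak:
    """Locate the early/late stage break of a drug time course.

    Grid search over observed time points: mean size is fitted linear in
    time up to the candidate break and constant after it; the break
    minimizing total squared error wins (ties go to the earliest).  A flat
    series (no transient) returns the fixed fallback, flagged.
    """
    t, _, s = _series_arrays(series)
    if len(t) < 6:
        raise ValueError("need at least 6 size time points")
    if np.ptp(s) <= 1e-12 * max(1.0, abs(s).max()):
        return StageBreak(fallback, True, 0.0, "no transient")

    best = None
    for b in t[min_points - 1 : len(t) - min_points + 1]:
        early = t <= b + _EPS
        late = t >= b - _EPS
        if early.sum() < min_points or late.sum() < min_points:
            continue
        fit = stats.linregress(t[early], s[early])
        sse_e = float(np.sum((s[early] - (fit.intercept + fit.slope * t[early])) ** 2))
        sse_l = float(np.sum((s[late] - s[late].mean()) ** 2))
        sse = sse_e + sse_l
        if best is None or sse < best[1] - _EPS:
            best = (float(b), sse)
    if best is None:
        return StageBreak(fallback, True, math.nan, "degenerate search")
    return StageBreak(best[0], False, best[1])


@dataclass
class CompensationEstimate:
    """Per-condition cycle length, growth rate and target size, by stage."""

    condition: str
    tau_early: float
    tau_late: float
    v_early: float
    v_late: float
    alpha_early: float
    alpha_late: float
    target_size: float  # C_TS = v_late * tau_late (homeostatic value)
    size_late: float  # mean size over the late stage (constant fit)
    stage_break: float
    size_fold_change: float | None = None
    cts_fold_change: float | None = None
    v_fold_early: float | None = None
    tau_fold_early: float | None = None
    v_fold_late: float | None = None
    tau_fold_late: float | None = None


def stagewise_estimates(
    series: pd.DataFrame,
    stage_break: float | StageBreak | None = None,
    condition: str | None = None,
) -> CompensationEstimate:
    """Independent early/late exponential fits of counts and bulk mass.

    The early stage spans the series start to the break, the late stage
    the break to the end.  The late-stage mean size comes from the
    constant (zero-slope) fit, i.e. the plain mean.
    """
    t, n, s = _series_arrays(series)
    if stage_break is None:
        stage_break = segment_stages(series)
    brk = stage_break.time if isinstance(stage_break, StageBreak) else float(stage_break)
    if condition is None:
        condition = str(series["condition"].iloc[0]) if "condition" in series else ""

    early = t <= brk + _EPS
    late = t >= brk - _EPS
    if early.sum() < 3 or late.sum() < 3:
        raise ValueError("each stage needs at least 3 points")

    a_e, tau_e, _ = fit_cycle_length(t[early], n[early])
    a_l, tau_l, _ = fit_cycle_length(t[late], n[late])
    v_e = growth_rate_bulk(series, (t[early][0], t[early][-1]))
    v_l = growth_rate_bulk(series, (t[late][0], t[late][-1]))
    size_late = float(s[late].mean())
    cts = v_l * tau_l if math.isfinite(tau_l) else math.inf
    return CompensationEstimate(
        condition=condition,
        tau_early=tau_e,
        tau_late=tau_l,
        v_early=v_e,
        v_late=v_l,
        alpha_early=a_e,
        alpha_late=a_l,
        target_size=cts,
        size_late=size_late,
        stage_break=brk,
    )


def single_stage_estimate(series: pd.DataFrame, condition: str | None = None) -> CompensationEstimate:
    """Whole-course fit (no early/late split); both stages carry the same values."""
    t, n, s = _series_arrays(series)
    if condition is None:
        condition = str(series["condition"].iloc[0]) if "condition" in series else ""
    a, tau, _ = fit_cycle_length(t, n)
    v = growth_rate_bulk(series)
    cts = v * tau if math.isfinite(tau) else math.inf
    return CompensationEstimate(
        condition=condition,
        tau_early=tau,
        tau_late=tau,
        v_early=v,
        v_late=v,
        alpha_early=a,
        alpha_late=a,
        target_size=cts,
        size_late=float(s.mean()),
        stage_break=t[0],
    )


@dataclass
class ConditionPanel:
    """A set of per-condition estimates normalized to a control reference."""

    estimates: list[CompensationEstimate]
    control: str
    control_v: float
    control_tau: float
    control_cts: float
    control_size: float
    loglog_r: float | None
    loglog_p: float | None
    outside_band: list[str]
    band: float


def target_size_panel(
    estimates: list[CompensationEstimate],
    control: str = "control",
    subset: list[str] | None = None,
    band: float = 0.25,
) -> ConditionPanel:
    """Normalize a condition panel to control and test v–τ compensation.

    Multiple control replicates are averaged before normalization.  The
    log–log Pearson correlation between relative growth rate and relative
    cycle length is computed over ``subset`` (default: all non-control
    conditions with finite τ).  Conditions whose C_TS fold change leaves
    the ±``band`` iso-size band are flagged.
    """
    ctrl = [e for e in estimates if e.condition == control]
    if not ctrl:
        raise ValueError(f"control condition {control!r} not found")
    cv = float(np.mean([e.v_late for e in ctrl]))
    ctau = float(np.mean([e.tau_late for e in ctrl]))
    ccts = float(np.mean([e.target_size for e in ctrl]))
    csize = float(np.mean([e.size_late for e in ctrl]))
    if cv <= 0 or not math.isfinite(ctau) or ctau <= 0:
        raise ValueError("control growth rate and cycle length must be positive finite")

    out: list[CompensationEstimate] = []
    for e in estimates:
        out.append(
            replace(
                e,
                v_fold_early=e.v_early / cv,
                tau_fold_early=(e.tau_early / ctau if math.isfinite(e.tau_early) else math.inf),
                v_fold_late=e.v_late / cv,
                tau_fold_late=(e.tau_late / ctau if math.isfinite(e.tau_late) else math.inf),
                cts_fold_change=(e.target_size / ccts if math.isfinite(e.target_size) else math.inf),
                size_fold_change=e.size_late / csize,
            )
        )

    if subset is None:
        pool = [e for e in out if e.condition != control and math.isfinite(e.tau_late)]
    else:
        pool = [e for e in out if e.condition in subset and math.isfinite(e.tau_late)]
    loglog_r = loglog_p = None
    if len(pool) >= 3:
        lv = np.log([e.v_fold_late for e in pool])
        lt = np.log([e.tau_fold_late for e in pool])
        if np.std(lv) > 0 and np.std(lt) > 0:
            r, p = stats.pearsonr(lv, lt)
            loglog_r, loglog_p = float(r), float(p)

    outside = [
        e.condition
        for e in out
        if e.condition != control
        and (not math.isfinite(e.cts_fold_change) or abs(math.log(e.cts_fold_change)) > math.log(1.0 + band))
    ]
    return ConditionPanel(
        estimates=out,
        control=control,
        control_v=cv,
        control_tau=ctau,
        control_cts=ccts,
        control_size=csize,
        loglog_r=loglog_r,
        loglog_p=loglog_p,
        outside_band=outside,
        band=band,
    )
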