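# Methods

This note documents the models and estimators implemented in `sizerkit`,
the defaults and calibrations of the synthetic-data generator, the
numerical choices, and what the tests do and do not establish about real
data.

## 1. The growth/division model (`growthsim`)

### State and time

Cells are points carrying (size S, birth time, birth size, phase,
persistent growth-rate factor ρ, persistent nucleus-proxy factor κ).
Time advances on a fixed grid (default 0.25 h, the cadence of a typical
15-minute time-lapse acquisition); all stochastic draws happen per step.
Identical (config, duration, seed) reproduce byte-identical outputs.
Random numbers come from named substreams (dynamics, measurement, founder
initialization, proxy factors) fanned out of one master seed, so turning
observers on or off never changes the dynamics.

### Growth

Three growth models, all expressed through an instantaneous rate that is
modulated multiplicatively:

| model | increment over dt | default |
|---|---|---|
| `linear` | μ·dt | — |
| `poisson-increment` | Poisson(μ·dt) | yes, μ = 5 units/h |
| `exponential` | μ·S·dt (μ a fraction/h) | — |

Each cell's rate carries a **persistent factor ρ ~ logNormal(mean 1, CV
`growth_rate_cv` = 0.20)** drawn at birth. This is the ingredient that
makes size variance grow with age in the absence of feedback — the premise
of the variance-based analysis — and its CV is what G_cv estimates when
growth is otherwise size-independent. Without durable rate heterogeneity,
within-age size variance in a simulated cohort stays close to the
measurement-noise floor and the variance analysis has nothing to measure.

**Size-sensing feedback** multiplies the rate by `(S*/S)^β` inside
configurable age windows (outside them β = 0). Each window carries its own
set point S*: a cell's "right size" is age-dependent, so the correction is
centred on the typical size at that point of the cycle (a single absolute
set point cannot brake mid-cycle cells, which all sit above any
newborn-scale target). The default windows,

* 4.0–6.5 h, β = 8, set point 130 size units,
* 10.5–15.5 h, β = 10, set point 175 size units,

mimic two periods of size-corrective growth regulation within one cycle.
Their strengths were calibrated once, jointly with `growth_rate_cv` and the
division asymmetry, to the package's own detection contract: in 100 seeded
runs of ~3000 cells, the G_cv analysis (Section 3) flags negative
excursions in **both** windows in ≥ 99 runs, while matched β = 0 runs stay
inside the confidence band in ≥ 95. The second window is wider and
stronger because persistent rate heterogeneity keeps regenerating size
variance; a late correction must out-compete it.

### Cell cycle

G1 exit follows one of three rules: **sizer** (exit at the first sample
time with S ≥ 155 units, subject to a 3 h minimum G1), **timer** (drawn
duration, Normal(10 h, 1.5 h), truncated at one step), or **adder**
(S − birth size ≥ 52 units). Post-G1 lasts Normal(10.5 h, 1.0 h), mitosis
0.5 h, so the default cycle averages ~21 h with G1 ≈ 10 h — a HeLa-like
parameterization in which S-entry falls near 10 h after birth. Division
splits the mother exactly: daughters get f·S and (1−f)·S with
f ~ Normal(0.5, 0.06) clipped to (0.2, 0.8). The asymmetry SD of 0.06
reflects the several-percent sister asymmetries seen in cultured mammalian
cells; clipping replaces true truncation because at this SD the bounds are
~7σ away. Cell death is not modelled.

### Measurement

The stained-size readout is S·(1+ε), ε ~ N(0, 0.05). The nucleus proxy is
γ·S^δ·κ·(1+η) with γ = δ = 1 by default, κ a **persistent** per-cell
factor (logNormal, CV `nucleus_noise_cv` = 0.22) and η a small per-frame
jitter (CV 0.01). Splitting the proxy noise into a durable component plus
frame jitter matters: purely frame-independent noise at the calibrated
level would make lagged nucleus-increment correlations collapse into
regression-to-the-mean artifacts, while a purely persistent factor leaves
cross-sectional behavior unchanged. The value 0.22 is a calibration: it
makes an asynchronous default-parameter snapshot show
r(stained size, nucleus) ≈ 0.68 (mean over six seeds), the fidelity
reported for nuclear area as a proxy of protein mass. With these defaults
the sizer-mode correlation between nucleus size at ~1.25 h and G1 length
comes out near −0.4.

### Initialization and perturbations

Founders are newborn G1 cells with logNormal sizes around S*/1.4 (CV
0.12). `founder_stagger` spreads their birth times uniformly over one
cycle so short runs reach an asynchronous, near-balanced age structure;
scenario datasets use a stagger of 21 h plus a two-cycle run. A
`Perturbation(onset, growth_scale, cycle_scale)` multiplies growth rates
by g and divides all subsequently drawn phase durations by c from the
onset on (sizer thresholds untouched) — an instantaneous step, so a
perturbed population re-equilibrates within roughly half a cycle, faster
than real drug responses where uptake and pathway kinetics spread the
transition over a day.

## 2. Age-resolved curves (`snapshot_stats`)

Mean size versus age uses Gaussian-kernel local-linear regression on a
uniform grid (default spacing 0.25 h, bandwidth 1.0 h; the examples and
acceptance analyses of variance curves use 1.5 h, appropriate for features
a few hours wide). The variance function is the standard two-stage
estimator: local-linear regression of squared residuals around the fitted
mean (population-variance convention). Negative variance point estimates
are clipped to zero with a warning. Grid points with kernel effective
sample size below 25 are reported as NaN rather than extrapolated; where
all weighted ages around a grid point coincide, the local-linear system is
singular and the estimator falls back to the local mean.

Confidence bands are cell-level bootstrap percentiles (defaults: 90% for
the mean, 70% for the variance). A resample is equivalent to multinomial
reweighting of the kernel design, so one precomputed kernel matrix serves
all replicates. G_cv bands use a **joint** bootstrap — each resample
re-fits both curves — at a 50% level by default.

G_cv itself is the lagged difference statistic of the README with default
lag 2.5 h; the sign convention is +√ΔVar/Δmean for ΔVar > 0,
−√|ΔVar|/Δmean for ΔVar < 0, and 0 at ΔVar = 0 (continuity convention).
Evaluation is suppressed where Δmean ≤ 0, where the statistic is
uninterpretable. The detection rule used by the acceptance analyses calls
an excursion when the 50% band's upper edge is below zero at ≥ 4
consecutive grid points, and only considers ages with a + lag ≤ 18 h: past
that, divisions (starting ~16 h under default kinetics) remove cells and
the cohort-growth premise of the decomposition fails.

The checkpoint contrast bins cells by age (1.5 h bins, ≥ 10 cells of each
phase class), detrends sizes by the bin-wise all-cell mean, and pools a
Welch t-test of post-G1 versus G1. The plateau flag regresses G1 sizes on
age over the last three qualifying bins and reports a plateau when that
slope is not clearly positive (below twice its standard error) or has bent
below half the early-bin G1 slope; the bend clause reflects that with
persistent growth heterogeneity the late G1 pool approaches its ceiling
asymptotically rather than going exactly flat.

`size_variability` is MAD/median without a consistency constant —
scale-free and robust, suited to comparing dispersion across conditions.

## 3. Track statistics (`track_stats`)

Tracks are trimmed of their first 1.25 h (post-mitotic nuclear flattening)
and end at mitosis onset; "size at birth" is operationalized as the first
retained sample. Birth-size/G1-length coupling reports Pearson r, the
Student-t p, an ordinary least-squares slope, and a permutation null
(shuffle G1 durations; add-one p). Age-resolved growth coupling
correlates N(a) with N(a+lag) − N(a) across cells per age on the sampling
grid (lag 2.5 h default, bins under 20 cells flagged undefined, zero
variance flagged rather than zero-filled). Extreme-group convergence sorts
cells by nucleus size at a sort age (default 10 h, k = 10 per tail, ties
broken by cell id) and reports the large-minus-small gap at the last
common age relative to the sort age.

For coupling analyses on synthetic tracks, note the generator caveats: the
persistent proxy factor κ inflates lagged-increment correlations upward
(bigger-κ cells show bigger increments in proxy units) and persistent ρ
makes growth genuinely size-correlated at later ages. The clean null for
"no coupling built in" is therefore a configuration with
`growth_rate_cv = 0` and `nucleus_noise_cv = 0`, which the tests use.

## 4. Bulk kinetics (`bulk_kinetics`)

Cycle length comes from least squares on (t, ln N); a non-positive slope
yields τ = +∞, flagged, so arrested conditions survive panel assembly.
The growth rate v = (1/N)·dM/dt is implemented as an exponential fit of
M = N·S̄ within the analysis window, evaluated at the window midpoint with
N interpolated geometrically (exact for exponential counts; a
finite-difference mode exists for comparison). Stage segmentation fits
mean size linear-in-time before a candidate break and constant after,
scanning observed time points (ties to the earliest; flat series fall back
to a fixed 24 h break, flagged). The target-size panel averages control
replicates, normalizes v and τ to control, computes C_TS = v·τ and its
fold change, flags conditions outside a ±25% iso-size band, and reports
the log–log Pearson correlation between relative v and relative τ.

On simulated steady-state populations these estimators recover the
realized cycle length within 2% and satisfy v·τ ≈ ln2·S̄ within 5%; on a
3×3 grid of growth (g ∈ {0.4, 0.55, 0.7}) × cycle (c ∈ {0.45, 0.6, 0.8})
perturbations with the sizer and feedback on, the C_TS fold change stays
below the larger applied axis fold for every cell of the grid. The
comparator is per-axis because a combined perturbation with g ≈ c cancels
in the uncompensated product v·τ, leaving nothing to buffer.

## 5. Scenario datasets and I/O (`workbench`)

Six deterministic scenarios parameterize the simulator for testing:
`null_timer` (no size sensing), `sizer`, `feedback_dips` (timer plus the
two feedback windows), `rapamycin_like` (growth scale 0.4 against a pure
sizer, so the drug's primary effect on growth rate is undiluted by fast
growth feedback), `sns_like` (cycle durations doubled, feedback on), and
`perfect_compensation_panel` (an exact analytic panel with v = C/τ, hence
log–log r = −1; counts are exact reals so the identity holds to float
precision). Tables travel as comma-separated UTF-8 with header rows;
assay-vocabulary columns ("cell age", "total SE-A647 intensity", "nucleus
size", reporter intensities) are translated by a column-mapping layer, and
when a snapshot carries a post-G1 reporter intensity instead of phase
labels, phases are called by Otsu thresholding of the log intensity. Rows
violating invariants are dropped with logged counts. Run manifests record
package version, config hash, master seed and input digests; reports are
sorted-key JSON with no timestamps, so identical inputs give identical
bytes.

## 6. What the synthetic data do and do not show

The generator emulates: balanced exponential proliferation with a
realistic age pyramid; sizer/timer/adder G1 control; persistent growth
heterogeneity; windowed growth feedback; noisy stain and nucleus-proxy
readouts; step drug perturbations. It does not emulate: cell death,
contact inhibition or confluence effects, gradual drug onset, nuclear
shape changes (the proxy exponent δ is configurable but defaults to 1),
mother–daughter inheritance of growth rate, or probabilistic size
thresholds. Passing tests therefore demonstrate that the estimators
recover known ground truth under this model's assumptions — power and
calibration — not that any particular real cell line obeys the model.
Numerical parity with published curves from any specific experiment is
not expected, since kernel and bandwidth choices behind such curves are
generally unstated; the tests assert qualitative signatures (checkpoint
contrast and plateau, two feedback dips, compensation) instead.

## 7. Problem sizes and numerical conventions

Test simulations use 750 founders staggered over one cycle and 42 h of
growth (~3000 cells at fixation) for variance analyses; 100-run ensembles
for the detection-rate checks; 500–3000 usable tracks for coupling
statistics (the null |r| bound uses 3000 tracks, where the Monte-Carlo SD
of a true-zero correlation is ~0.02); and 60–100 founders over 84–120 h
for bulk estimation. Population-variance (ddof = 0) conventions are used
throughout the decomposition identities. Permutation p-values use the
add-one convention. Bootstrap resamples derive deterministically from the
analysis seed.
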