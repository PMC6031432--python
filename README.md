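# sizerkit

Tools for asking whether proliferating animal cells *sense their own size* —
and for quantifying the two strategies they use to correct it: size-dependent
G1 length and size-dependent growth rate.

The package is aimed at quantitative cell biologists working with
fix-and-stain snapshots (per-cell age, stained protein mass, cell-cycle
phase), live-cell nucleus-size tracks, and bulk proliferation time courses.
It couples a stochastic single-cell growth/division simulator — which can be
switched between sizer, timer and adder G1 rules, with or without
growth-rate feedback — to the statistical estimators that detect size
sensing in such data.

## The statistics at the core

**Variance-based growth-feedback detection.** For cells growing from size
S₁ to S₂ = S₁ + ΔS over an age interval,

```
Var(S₂) = Var(S₁) + Var(ΔS) + 2 Cov(S₁, ΔS)
```

holds exactly, so size variance can *decrease while cells grow* only if
Cov(S₁, ΔS) < 0 — small cells growing faster than large ones. The signed
**coefficient of growth-rate variation**

```
G_cv(a) = ± sqrt(|ΔVar(S)|) / (S̄₂ − S̄₁)        (sign of ΔVar)
```

is computed from age-resolved mean and variance curves (Gaussian-kernel
local-linear regression; cell-level joint bootstrap for confidence bands).
When growth is size-independent, G_cv equals the CV of the growth
increments, σ_gr/μ_gr (exactly 1 for a unit-rate Poisson growth process);
negative excursions diagnose size-dependent growth-rate correction.

**Cell-cycle-side size sensing.** Age-matched contrast of post-G1 vs G1
mean size (Welch test on age-detrended sizes), the plateau of the G1
mean-size curve, and the correlation of nucleus size at birth with G1
duration (Pearson r with a Student-t p and a permutation null).

**Population-level compensation.** From cell counts N_t and mean size S̄_t:
cycle length τ from exponential fits N_t = N₀e^{αt} (α = ln2/τ), growth
rate v = (1/N_t)·dM_t/dt with bulk mass M_t = N_t·S̄_t, early/late stage
segmentation of drug time courses, and the target size C_TS = v·τ whose
invariance across perturbations (iso-size contours v = C_TS/τ, log–log
v–τ correlation) is the signature of homeostatic coordination.

## Worked example

```python
import numpy as np
from sizerkit.growthsim import SimConfig, simulate
from sizerkit.snapshot_stats import checkpoint_contrast, doubling_ratio
from sizerkit.track_stats import TrackSet, birth_size_g1_correlation

cfg = SimConfig(g1_exit_rule="sizer", seed=0)       # G1 size threshold on
res = simulate(cfg, 42.0, 400, founder_stagger=21.0)

snap = res.snapshot
print(f"cells at fixation: {len(snap)}")
print(f"r(size, nucleus) = {np.corrcoef(snap.size_au, snap.nucleus_au)[0,1]:.2f}")
ck = checkpoint_contrast(snap)
print(f"post-G1 vs G1 contrast: t = {ck.t_statistic:.1f}, p = {ck.p_value:.2e}, "
      f"plateau = {ck.plateau_flag}")
print(f"mitotic/newborn size ratio = {doubling_ratio(snap):.2f}")

tracks = TrackSet(res.track_samples, res.track_events)
rep = birth_size_g1_correlation(tracks, n_perm=999, seed=0)
print(f"birth size vs G1 length: r = {rep.r:.2f} "
      f"(n = {rep.n}, permutation p = {rep.permutation_p:.3f})")
```

prints

```
cells at fixation: 1794
r(size, nucleus) = 0.68
post-G1 vs G1 contrast: t = 23.5, p = 5.18e-94, plateau = True
mitotic/newborn size ratio = 1.90
birth size vs G1 length: r = -0.36 (n = 1924, permutation p = 0.001)
```

Read: the nucleus proxy tracks stained size (r ≈ 0.68); post-G1 cells are
significantly larger than G1 cells *of the same age* and the G1 mean-size
curve plateaus — both signatures of a size threshold gating S-phase entry;
cells roughly double over a cycle; and small-born cells spend longer in G1
(r ≈ −0.36). Running the same analyses on a `g1_exit_rule="timer"`
simulation gives a flat contrast and r ≈ 0.

A command-line interface mirrors the library:

```bash
sizerkit simulate --duration 42 --founders 400 --stagger 21 --seed 0 --out run/
sizerkit snapshot-analyze --in run/snapshot.csv --out run/snap/
sizerkit tracks-analyze   --in run/ --perm 9999 --seed 0 --out run/tracks/
sizerkit bulk-analyze     --in run/bulk.csv --control control --out run/bulk/
```

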