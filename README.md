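# pitgrowth

Longitudinal pituitary volumetry across pregnancy: within-subject
ensemble segmentation of the anterior/posterior pituitary over many
MRI sessions, person-centred feature extraction, and nonlinear
trajectory modelling with derivative-based localisation of growth
phases.

## The problem

The anterior pituitary enlarges substantially during pregnancy
(lactotrope expansion under rising prolactin demand) and returns to
baseline postpartum, but the *trajectory* — when growth starts, dips,
peaks and reverses — can only be resolved by scanning the same person
many times from preconception through the postpartum year. Two
methodological problems follow:

1. **Border noise.** Manual lobe tracings fluctuate session to
   session. Here every other session of a subject is co-registered to
   each target session (affine + symmetric demons), labels are
   propagated, and a per-voxel **majority vote** over the ensemble
   (native tracing included; ties to the native label) defines
   regularised borders.
2. **Trajectory inference.** Per-subject z-scored volume `y_ij` at
   gestational week `t_ij` is modelled as a penalized-spline mixed
   model (GAMM),

   ```
   y_ij = f(t_ij) + b_i + e_ij,   b_i ~ N(0, σ_b²),
   cov(e_ij, e_ik) = σ_e² ρ^|t_ij − t_ik|      (CAR(1))
   ```

   with `f` a cubic B-spline (k = 10) and curvature penalty, estimated
   jointly with (λ, ρ, σ_b²/σ_e²) by REML. Periods of significant
   change are grid runs where the pointwise 95% band of `f̂′` excludes
   zero; the dip/peak are sign changes of `f̂′`. Early (−5–12 wk) and
   late (12–40 wk) windows get random-intercept line fits, and
   out-of-sample value is assessed by leave-one-subject-out prediction
   from the fixed effects.

Because such study scans are typically request-only, a first-class
synthetic module generates voxel phantoms and tabular cohorts with
exactly this generative structure (default: 3 subjects × 20 sessions,
a dip of −0.9 SD near week 10.6 and a peak of +1.8 SD near week 34.1,
ρ = 0.34), so the whole pipeline is testable offline. See
`docs/methods.md` for model details and assumptions.

## Worked example

```python
from pitgrowth import (TrajectoryTruth, simulate_feature_table,
                       add_person_centered_columns, fit_gamm,
                       derivative_inference, principal_extrema,
                       fit_window_lmm)

table = add_person_centered_columns(simulate_feature_table(TrajectoryTruth(seed=0)))
fit = fit_gamm(table, "z_vol_anterior")
ext = principal_extrema(derivative_inference(fit))
print(f"edf={fit.edf:.2f} adjR2={fit.adj_r2:.2f} rho={fit.rho:.2f}")
print(f"dip  {ext['min']['value_sd']:+.2f} SD at week {ext['min']['week']:.1f}")
print(f"peak {ext['max']['value_sd']:+.2f} SD at week {ext['max']['week']:.1f}")
print(f"late-window slope {fit_window_lmm(table, 12, 40).slope:+.3f} SD/week")
```

prints (seed 0):

```
edf=7.37 adjR2=0.83 rho=0.44
dip  -1.19 SD at week 9.5
peak +1.54 SD at week 35.2
late-window slope +0.123 SD/week
```

— the fitted anterior trajectory dips at the end of the first
trimester, rises steeply to a peak in the third trimester (here +1.5
SD at week 35), and the late-pregnancy window gains ~0.12 SD of volume
per week; the posterior lobe, fitted the same way, stays flat
(`p_smooth` ≈ 0.4).

The numbered drivers under `analysis/` run the same steps as a
narrative: `01_simulate_cohort.py` (cohort table), `02_segmentation_
ensemble.py` (phantom registration + fusion QC), `03_fit_trajectories.py`
(fits, derivative bands, windows, LOSO), `04_recovery_experiment.py`
(50-replicate Monte-Carlo recovery). Outputs land in `results/`. A
`pitgrowth` CLI (`simulate`, `segment`, `extract`, `fit`, `report`,
`run-all`) wraps the same library calls for shell use.

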