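# Methods

`pitgrowth` models anterior-pituitary growth across pregnancy from
densely sampled longitudinal MRI: an ensemble-segmentation stage that
regularises per-session lobe borders, a feature stage that reduces each
session to volumes and signal summaries, and a trajectory stage that
fits a nonlinear mixed model over gestational weeks and localises
growth phases from its first derivative. Because the motivating study's
scans are available only on request, a synthetic-data module generates
both voxel phantoms and tabular series with the statistical structure
the models assume, so every stage is testable end to end.

## Time axis

All stages use a single continuous axis, *weeks relative to
conception*: preconception weeks are negative, delivery is placed at
the subject's gestational length (39 weeks when unknown), and a
postpartum visit at *w* weeks after delivery sits at `39 + w`. Phase
labels (preconception / pregnancy / postpartum) derive from this axis.
Real dense-sampling designs report preconception and postpartum offsets
separately; collapsing them onto one axis is a convention of this
package, not a property of the data.

## Synthetic data

**Tabular generator.** For subject *i* at week *t*,

    y_ij = f(t_ij) + b_i + e_ij,   b_i ~ N(0, σ_b²),
    cov(e_ij, e_ik) = σ_e² ρ^|t_ij − t_ik|        (continuous AR(1)).

`f` is a fixed clamped cubic spline through documented knots
(`DEFAULT_TRAJECTORY_KNOTS`), giving a dip of −0.9 SD near week 10.6, a
peak of +1.8 SD near week 34.1 (true extrema of the interpolant: week
10.1 and 34.0), and a return to baseline before conception and by ~3
months after delivery. Defaults: 3 subjects × 20 sessions, σ_b = 0.3,
σ_e = 0.45, ρ = 0.34/week. Raw volumes are `raw = μ_i + s_i·y` with
per-subject (μ, s) of (525, 29), (799, 68), (799, 41) mm³ anterior and
~92–103 mm³ posterior; the posterior series uses a flat `f ≡ 0`.

**Visit design.** Each subject gets 2 preconception, 13 pregnancy and
5 postpartum visits on a fixed base grid spanning −12 to +90 weeks,
jittered by ±1 week — matching the per-subject session counts and phase
coverage of dense-sampling pregnancy cohorts (≈3-week pregnancy gaps).
A consequence worth knowing: with ~3-week gaps, a per-week correlation
of ρ = 0.34 implies adjacent-visit correlations of ρ³ ≈ 0.04, so ρ is
near the edge of identifiability; REML (and R's `mgcv::gamm`, against
which the fitter is cross-checked) returns ρ̂ = 0 in roughly half of
simulated replicates. Monte-Carlo summaries of ρ̂ should therefore be
read as information-limited under this design; recovery is assessed on
the generative response scale, since re-person-centring a simulated
series removes each subject's mean and scale and with it part of the
correlation signal.

**Voxel phantoms.** Two disjoint ellipsoids on a 48³ grid at 0.8 mm
isotropic: anterior (semiaxes 7.5 × 6.0 × 3.5 mm, ≈660 mm³, intensity
200) and posterior (3.5 × 3.25 × 2.0 mm, ≈95 mm³, intensity 400 —
posterior hyperintense at 2× anterior, background 100), additive
Gaussian intensity noise (SD 10). Per session the anterior semiaxes are
scaled by the cube root of the trajectory's relative raw volume, and a
smooth random warp (sum of three Gaussian-bump displacement fields,
width 6 mm, peak magnitude `deformation_scale_mm`, default 0.5 mm) is
applied by pull-back. Labels use voxel-centre membership — no
anti-aliasing, so voxel-counted volumes match the analytic
`4/3·π·abc` only to ~1–2% at this resolution, absorbed by the 5%
analytic-oracle tolerance. The generator refuses geometries whose
scaled lobes reach the grid boundary. Not emulated: MRI physics (bias
fields, susceptibility), surrounding anatomy, partial-volume blur —
passing phantoms therefore demonstrates algorithmic correctness, not
robustness to scanner artefacts.

A separate `jitter_labels` utility emulates per-session tracing noise
by perturbing each lobe's signed distance map with a smooth random
field and re-thresholding (overlaps go to the lobe with the more
negative perturbed distance).

## Segmentation ensemble

Within a subject, every other session is registered to a target
session; their label maps are propagated (nearest-neighbour) and
combined with the target's native labels by per-voxel majority vote.
Background is a first-class label — a voxel can be voted out of the
gland. Exact ties go to the native label (preserving the expert
delineation where the ensemble is uninformative); ties not involving
the native label resolve to the lowest label code. Vote counts, tie
counts, fused lobe volumes and Dice against the native labels are
reported per session.

Registration is affine (multi-resolution mean-squares, 3 levels,
regular-step gradient descent) optionally followed by a fast
symmetric-forces demons stage (150 iterations, 0.8 mm field smoothing,
0.25 mm image pre-smoothing), both via SimpleITK. Transforms are
stored backend-agnostically — a 4×4 affine in mm plus an optional dense
displacement field on the fixed grid with its numerical inverse — so
externally computed transforms can be substituted. Inverse-consistency
(mean round-trip displacement) is reported; ~0.2 voxel is typical on
phantoms. Optimiser iteration caps are flagged as warnings rather than
errors: on piecewise-constant phantoms the metric plateau is reached
long before the cap matters.

## Features

Per session: lobe volumes (voxel count × voxel volume), median in-mask
intensity per lobe (even counts: midpoint convention), and a
two-sample t contrast of posterior minus anterior voxel intensities.
Welch (unequal variance) is the default — the lobes' variances clearly
differ; pooled is available. Voxel samples come from the *fused* masks.
Person-centring z-scores each subject's series with its own mean and
sample SD (n−1) over all sessions, preconception through postpartum;
zero-SD series yield zeros with a warning.

## Trajectory model

For a response `y` (person-centred or generative-scale),

    y = B(t)β + Z b + e,   b ~ N(0, σ_b² I),   e ~ N(0, σ_e² C(ρ)),

with `B` a cubic B-spline basis of dimension k = 10 (interior knots at
quantiles of the observed weeks) and a curvature penalty
`λ βᵀSβ`, `S = ∫ B″(t)B″(t)ᵀ dt` computed exactly by two-point
Gauss–Legendre per knot span. The penalty's null space is exactly
{constant, line}, so λ → ∞ collapses the fit onto the generalised
least-squares line — a useful closed-form limit that a coefficient
difference penalty on non-uniform knots would only approximate, which
is why the curvature form was chosen.

**Estimation.** For fixed (λ, ρ, γ = σ_b²/σ_e²) the model is whitened
by the Cholesky factor of `W = C(ρ) + γ11ᵀ` (block-diagonal over
subjects) and the penalised solution is closed-form; σ_e² is profiled
and the restricted likelihood

    −2·l_R = (n−2)[log 2πσ̂² + 1] + log|W| + log|X̃ᵀX̃ + λS| − log|λS|₊

is minimised over (log λ, logit ρ, log γ) by Nelder–Mead from three
fixed starting points (λ, ρ, γ) ∈ {(1, .3, 1), (e⁶, .05, e⁻²),
(e⁻³, .6, e)}; the fit is deterministic given data, and exact criterion
ties resolve to the smallest λ. Reported: smooth edf (trace of the hat
contribution minus the constant, so a pure line has edf 1), adjusted
R² = 1 − (RSS/(n − edf_model − 1))/(TSS/(n − 1)) with RSS from fixed +
shrunk-intercept fitted values, an approximate Wald F for the smooth
(centred fitted values against their Bayesian covariance at rank
⌈edf⌉; calibrated at ~5.5% empirical size at the 0.05 level under a
flat-truth null over 200 replicates), and an AIC from the marginal
Gaussian likelihood with an edf-based parameter count. Bonferroni
correction multiplies smooth p-values by the number of trajectory
models in a run (default 2, configurable).

**Derivative inference.** f̂′ on a 0.1-week grid by exact B-spline
differentiation; pointwise 95% normal bands from the Bayesian
coefficient covariance (simultaneous bands are not implemented);
*significant change* = maximal grid runs where the band excludes zero;
*extrema* = sign changes of f̂′, located by linear interpolation, with
the fitted value at that week. `principal_extrema` picks the deepest
minimum and highest maximum.

**Window models.** Random-intercept lines within early (−5 to 12
weeks) and late (12 to 40 weeks) windows via statsmodels `MixedLM`
(REML), reporting slope (SD/week), SE and Wald p. A noiseless shared
line is detected and returned exactly (the mixed model would sit on a
variance boundary there).

**Leave-one-subject-out.** Each fold refits on the remaining subjects
and predicts the held-out subject from the smooth alone (random
intercept 0 — valid for person-centred responses); fold
R² = 1 − SSE/SST with SST about the held-out subject's own mean. With
3 subjects each fold trains on 2.

**Diagnostics.** Raw and CAR(1)-whitened lag-1 residual
autocorrelation over time-adjacent within-subject pairs (whitened ≈ 0
when the correlation structure is captured; informative only when the
visit spacing makes dependence visible at lag 1), Shapiro normality p,
and per-subject residual means. This replaces basis-dimension
diagnostics tied to a specific smoothing package.

## Problem sizes and defaults in the shipped runs

The demo pipeline couples a voxel branch at reduced size (1 subject ×
5 sessions, 48³) — full k = 10 smooths need ~20 sessions per subject,
and an all-pairs registration ensemble at 20 sessions would dominate
the runtime without changing what the voxel branch demonstrates — with
a full-length tabular simulation (3 × 20) for the trajectory stage.
Monte-Carlo experiments use 50 replicates with seed streams derived
from `numpy.random.SeedSequence`. All tables and JSON outputs are
bit-reproducible for a fixed seed; a run directory carries a manifest
with a config hash and per-file checksums.

## Known limitations

- Phantoms are piecewise-constant ellipsoids; registration and fusion
  results on them bound algorithmic correctness, not clinical accuracy.
- ρ is weakly identified under ~3-week visit spacing (see above); its
  point estimate should not be over-read at this design, mirroring the
  general caution needed for correlation parameters in small dense-
  sampling cohorts.
- The smooth-term test and derivative bands ignore smoothing-parameter
  uncertainty, the standard approximation in penalized additive models.
- With 3 subjects, between-subject generalisation rests entirely on
  the leave-one-subject-out numbers; the in-sample adjusted R² is
  optimistic by construction.
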