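"""Synthetic longitudinal pituitary data.

Two generators stand in for the study data (scans of three women densely
sampled from preconception through one year postpartum, which are not
publicly deposited):

* :func:`simulate_feature_table` draws tabular session series with the
  exact statistical structure the trajectory model assumes — a shared
  nonlinear mean over gestational weeks, Gaussian subject intercepts and
  continuous-AR(1) residual correlation (``corr = rho**|dt|`` in weeks).
* :func:`simulate_image_series` renders per-session voxel phantoms: two
  disjoint ellipsoids (anterior and posterior lobes) on a T1-like
  background, with the anterior lobe rescaled each session so its
  analytic volume tracks the trajectory, an optional smooth random warp,
  and additive intensity noise.  Ground-truth label maps and analytic
  volumes are emitted alongside.

The default trajectory is a fixed clamped cubic spline with a dip of
−0.9 SD near gestational week 10.6 and a peak of +1.8 SD near week
34.1, returning to baseline postpartum; the default generator settings
(3 subjects × 20 sessions, rho = 0.34, residual SD = 0.45, intercept
SD = 0.3) mirror the magnitudes reported for anterior pituitary volume
in densely sampled pregnancy cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .volumes import ANTERIOR, BACKGROUND, POSTERIOR, ImageVolume, LabelMap

# Fixed knots of the default standardized anterior-volume trajectory
# (weeks relative to conception -> SD units).  Documented constants of
# the package; chosen to place a local minimum of -0.9 SD near week
# 10.6 and a local maximum of +1.8 SD near week 34.1 with a return to
# baseline before conception and by ~3 months after delivery.
DEFAULT_TRAJECTORY_KNOTS: tuple[tuple[float, float], ...] = (
    (-18.0, 0.0),
    (-5.0, 0.0),
    (0.0, -0.2),
    (10.6, -0.9),
    (22.0, 0.5),
    (34.1, 1.8),
    (38.0, 1.68),
    (40.0, 1.6),
    (52.0, 0.2),
    (62.0, 0.02),
    (75.0, 0.0),
    (90.0, 0.0),
)

DEFAULT_GESTATIONAL_LENGTH_WEEKS = 39.0

# Per-subject raw anterior/posterior volume scales (mm^3), bracketing
# published per-participant means and SDs.
DEFAULT_ANTERIOR_RAW_MEAN = (525.0, 799.0, 799.0)
DEFAULT_ANTERIOR_RAW_SD = (29.0, 68.0, 41.0)
DEFAULT_POSTERIOR_RAW_MEAN = (92.0, 100.0, 103.0)
DEFAULT_POSTERIOR_RAW_SD = (6.0, 8.0, 4.0)

# Base observation design per subject: 2 preconception, 13 pregnancy and
# 5 postpartum visits (weeks relative to conception); actual visit times
# are jittered around these.
BASE_SESSION_WEEKS: tuple[float, ...] = (
    -12.0, -3.0,
    1.0, 4.0, 7.0, 10.0, 13.0, 16.0, 19.0, 22.0, 25.0, 28.0, 31.0, 34.0, 36.0,
    45.0, 53.0, 62.0, 74.0, 90.0,
)


def make_default_trajectory() -> Callable[[np.ndarray], np.ndarray]:
    """Return the default weeks -> standardized anterior volume function.

    A C² clamped cubic spline (zero slope at both ends) through
    :data:`DEFAULT_TRAJECTORY_KNOTS`; evaluates to 0 outside the knot
    range.
    """
    knots = np.array(DEFAULT_TRAJECTORY_KNOTS)
    spline = CubicSpline(knots[:, 0], knots[:, 1], bc_type=((1, 0.0), (1, 0.0)))
    lo, hi = knots[0, 0], knots[-1, 0]

    def f(weeks):
        w = np.asarray(weeks, dtype=float)
        out = np.where((w < lo) | (w > hi), 0.0, spline(np.clip(w, lo, hi)))
        return float(out) if np.isscalar(weeks) else out

    return f


def flat_trajectory() -> Callable[[np.ndarray], np.ndarray]:
    """The null (posterior-lobe) trajectory: identically zero."""

    def f(weeks):
        w = np.asarray(weeks, dtype=float)
        out = np.zeros_like(w)
        return float(out) if np.isscalar(weeks) else out

    return f


@dataclass
class TrajectoryTruth:
    """Ground-truth settings for the tabular longitudinal generator."""

    f_true: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=make_default_trajectory
    )
    subject_intercept_sd: float = 0.3
    residual_sd: float = 0.45
    rho: float = 0.34
    n_subjects: int = 3
    sessions_per_subject: int = 20
    time_sampling: Sequence[float] | None = None
    time_jitter_weeks: float = 1.0
    raw_mean_mm3: Sequence[float] = DEFAULT_ANTERIOR_RAW_MEAN
    raw_sd_mm3: Sequence[float] = DEFAULT_ANTERIOR_RAW_SD
    gestational_length_weeks: float = DEFAULT_GESTATIONAL_LENGTH_WEEKS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.subject_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_subjects < 1 or self.sessions_per_subject < 1:
            raise ValueError("need at least one subject and one session")

    def subject_weeks(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one subject's observation weeks (sorted)."""
        if self.time_sampling is not None:
            base = np.asarray(self.time_sampling, dtype=float)
        else:
            base = np.asarray(BASE_SESSION_WEEKS, dtype=float)
        if len(base) < self.sessions_per_subject:
            # evenly resample the design to the requested session count
            base = np.interp(
                np.linspace(0, len(base) - 1, self.sessions_per_subject),
                np.arange(len(base)),
                base,
            )
        else:
            base = base[: self.sessions_per_subject]
        jitter = rng.uniform(-self.time_jitter_weeks, self.time_jitter_weeks, base.size)
        return np.sort(base + jitter)


def phase_of_week(weeks: float, gestational_length: float = DEFAULT_GESTATIONAL_LENGTH_WEEKS) -> str:
    if weeks < 0:
        return "preconception"
    if weeks < gestational_length:
        return "pregnancy"
    return "postpartum"


def simulate_feature_table(truth: TrajectoryTruth) -> pd.DataFrame:
    """Simulate the longitudinal session table for all subjects.

    Per subject i and visit time t_ij the standardized anterior response
    is ``y_ij = f_true(t_ij) + b_i + e_ij`` with ``b_i ~ N(0, sd_b^2)``
    and within-subject residual covariance
    ``cov(e_ij, e_ik) = sd_e^2 * rho**|t_ij - t_ik|``.  A flat posterior
    series with the same error structure, raw-volume columns mapped
    through per-subject (mean, SD) scales, and noiseless T1-like median
    intensity columns (posterior ~2x anterior) are attached.
    """
    from .gamm import car1_correlation  # local import avoids module cycle

    rng = np.random.default_rng(truth.seed)
    f_post = flat_trajectory()
    rows = []
    for i in range(truth.n_subjects):
        weeks = truth.subject_weeks(rng)
        m = len(weeks)
        corr = car1_correlation(weeks, truth.rho)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(m))
        b_ant = rng.normal(0.0, truth.subject_intercept_sd)
        e_ant = truth.residual_sd * (chol @ rng.standard_normal(m))
        b_post = rng.normal(0.0, truth.subject_intercept_sd)
        e_post = truth.residual_sd * (chol @ rng.standard_normal(m))
        y_ant = truth.f_true(weeks) + b_ant + e_ant
        y_post = f_post(weeks) + b_post + e_post
        ant_mu = truth.raw_mean_mm3[i % len(truth.raw_mean_mm3)]
        ant_sd = truth.raw_sd_mm3[i % len(truth.raw_sd_mm3)]
        post_mu = DEFAULT_POSTERIOR_RAW_MEAN[i % len(DEFAULT_POSTERIOR_RAW_MEAN)]
        post_sd = DEFAULT_POSTERIOR_RAW_SD[i % len(DEFAULT_POSTERIOR_RAW_SD)]
        for j in range(m):
            rows.append(
                {
                    "subject_id": f"sub-{i + 1:02d}",
                    "session_id": f"ses-{j + 1:02d}",
                    "weeks": weeks[j],
                    "phase": phase_of_week(weeks[j], truth.gestational_length_weeks),
                    "y_anterior": y_ant[j],
                    "y_posterior": y_post[j],
                    "vol_anterior_mm3": ant_mu + ant_sd * y_ant[j],
                    "vol_posterior_mm3": post_mu + post_sd * y_post[j],
                    "median_int_anterior": 200.0,
                    "median_int_posterior": 400.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry and intensity settings for the two-lobe voxel phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 0.8
    anterior_semiaxes_mm: tuple[float, float, float] = (7.5, 6.0, 3.5)
    posterior_semiaxes_mm: tuple[float, float, float] = (3.5, 3.25, 2.0)
    anterior_center_mm: tuple[float, float, float] = (17.0, 19.2, 19.2)
    posterior_center_mm: tuple[float, float, float] = (30.0, 19.2, 19.2)
    intensity_anterior: float = 200.0
    intensity_posterior: float = 400.0
    intensity_background: float = 100.0
    noise_sd: float = 10.0
    deformation_scale_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for ax in (self.anterior_semiaxes_mm, self.posterior_semiaxes_mm):
            if any(a <= 0 for a in ax):
                raise ValueError("ellipsoid semiaxes must be positive")
        if self.intensity_posterior <= self.intensity_anterior:
            raise ValueError(
                "posterior lobe must be hyperintense relative to anterior"
            )
        if self._lobes_overlap(1.0):
            raise ValueError("anterior and posterior ellipsoids overlap at scale 1")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3

    @property
    def fov_mm(self) -> np.ndarray:
        return np.array(self.grid_shape) * self.voxel_size_mm

    def anterior_volume_mm3(self, scale: float = 1.0) -> float:
        a, b, c = self.anterior_semiaxes_mm
        return 4.0 / 3.0 * np.pi * a * b * c * scale**3

    def posterior_volume_mm3(self) -> float:
        a, b, c = self.posterior_semiaxes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def _lobes_overlap(self, anterior_scale: float) -> bool:
        # conservative bounding-box check along each axis
        ca = np.array(self.anterior_center_mm)
        cp = np.array(self.posterior_center_mm)
        ra = np.array(self.anterior_semiaxes_mm) * anterior_scale
        rp = np.array(self.posterior_semiaxes_mm)
        return bool(np.all(np.abs(ca - cp) < ra + rp))

    def check_in_bounds(self, anterior_scale: float, margin_mm: float = 0.0) -> None:
        """Raise if a (scaled) lobe reaches the grid boundary."""
        for center, semi, scale, name in (
            (self.anterior_center_mm, self.anterior_semiaxes_mm, anterior_scale, "anterior"),
            (self.posterior_center_mm, self.posterior_semiaxes_mm, 1.0, "posterior"),
        ):
            c = np.array(center)
            r = np.array(semi) * scale + margin_mm
            if np.any(c - r < 0) or np.any(c + r > self.fov_mm):
                raise ValueError(
                    f"{name} lobe (scale {scale:.3f}) intersects the grid boundary"
                )


def _voxel_centers_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * spec.voxel_size_mm for n in spec.grid_shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def _gaussian_bump_warp(
    spec: PhantomSpec, rng: np.random.Generator, n_bumps: int = 3, width_mm: float = 6.0
):
    """Smooth random displacement: sum of Gaussian bumps, |u| <= scale."""
    fov = spec.fov_mm
    centers = rng.uniform(0.25 * fov, 0.75 * fov, size=(n_bumps, 3))
    amps = rng.standard_normal((n_bumps, 3))
    norms = np.linalg.norm(amps, axis=1, keepdims=True)
    # per-bump peak displacement ~ deformation_scale_mm (bumps rarely align)
    amps = amps / np.maximum(norms, 1e-12) * spec.deformation_scale_mm * rng.uniform(
        0.6, 1.0, size=(n_bumps, 1)
    )

    def warp(xx, yy, zz):
        ux = np.zeros_like(xx)
        uy = np.zeros_like(xx)
        uz = np.zeros_like(xx)
        for c, a in zip(centers, amps):
            g = np.exp(
                -((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
                / (2.0 * width_mm**2)
            )
            ux += a[0] * g
            uy += a[1] * g
            uz += a[2] * g
        return ux, uy, uz

    return warp


def render_session(
    spec: PhantomSpec,
    anterior_scale: float = 1.0,
    warp=None,
    rng: np.random.Generator | None = None,
) -> tuple[ImageVolume, LabelMap]:
    """Render one session: labels by voxel-center membership, then image."""
    spec.check_in_bounds(anterior_scale, margin_mm=spec.deformation_scale_mm)
    xx, yy, zz = _voxel_centers_mm(spec)
    if warp is not None:
        ux, uy, uz = warp(xx, yy, zz)
        xx, yy, zz = xx + ux, yy + uy, zz + uz
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for code, center, semi, scale in (
        (ANTERIOR, spec.anterior_center_mm, spec.anterior_semiaxes_mm, anterior_scale),
        (POSTERIOR, spec.posterior_center_mm, spec.posterior_semiaxes_mm, 1.0),
    ):
        a, b, c = (np.array(semi) * scale).tolist()
        inside = (
            ((xx - center[0]) / a) ** 2
            + ((yy - center[1]) / b) ** 2
            + ((zz - center[2]) / c) ** 2
        ) <= 1.0
        labels[inside] = code
    intensity = np.full(spec.grid_shape, spec.intensity_background)
    intensity[labels == ANTERIOR] = spec.intensity_anterior
    intensity[labels == POSTERIOR] = spec.intensity_posterior
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    return (
        ImageVolume(intensity, spec.spacing),
        LabelMap(labels, spec.spacing),
    )


def simulate_image_series(
    spec: PhantomSpec,
    truth: TrajectoryTruth,
    subject: int = 0,
) -> list[dict]:
    """Simulate one subject's multi-session image/label series.

    Returns one dict per session with keys ``weeks``, ``image``,
    ``labels``, ``true_vol_anterior_mm3``, ``true_vol_posterior_mm3``
    and ``anterior_scale``.  The anterior ellipsoid is rescaled so its
    analytic volume tracks the subject's raw trajectory volume; each
    session gets its own smooth random warp of magnitude
    ``deformation_scale_mm`` and fresh intensity noise.
    """
    table = simulate_feature_table(truth)
    sub_ids = sorted(table["subject_id"].unique())
    if subject >= len(sub_ids):
        raise ValueError(f"subject index {subject} out of range")
    sub = table[table["subject_id"] == sub_ids[subject]].reset_index(drop=True)
    if len(sub) < 3:
        raise ValueError("need at least 3 sessions per subject")
    rng = np.random.default_rng(spec.seed + 1000 * subject)
    raw_mu = truth.raw_mean_mm3[subject % len(truth.raw_mean_mm3)]
    base_vol = spec.anterior_volume_mm3()
    sessions = []
    for _, row in sub.iterrows():
        # track the trajectory in relative terms so the phantom's own
        # base volume plays the role of the subject's mean volume
        rel = row["vol_anterior_mm3"] / raw_mu
        scale = float(np.cbrt(rel))
        warp = (
            _gaussian_bump_warp(spec, rng)
            if spec.deformation_scale_mm > 0
            else None
        )
        image, labels = render_session(spec, anterior_scale=scale, warp=warp, rng=rng)
        sessions.append(
            {
                "session_id": row["session_id"],
                "weeks": row["weeks"],
                "image": image,
                "labels": labels,
                "anterior_scale": scale,
                "true_vol_anterior_mm3": base_vol * scale**3,
                "true_vol_posterior_mm3": spec.posterior_volume_mm3(),
            }
        )
    return sessions


def jitter_labels(
    labels: LabelMap, amplitude_mm: float, rng: np.random.Generator,
    smooth_sigma_vox: float = 2.0,
) -> LabelMap:
    """Perturb lobe borders with a smooth random field.

    Emulates per-session tracing noise: each lobe's signed Euclidean
    distance map (mm, negative inside) is shifted by a unit-variance
    smoothed Gaussian field scaled to ``amplitude_mm`` and re-thresholded.
    Voxels claimed by both lobes go to the one with the more negative
    perturbed distance.
    """
    spacing = labels.spacing
    noise = ndimage.gaussian_filter(
        rng.standard_normal(labels.shape), smooth_sigma_vox
    )
    noise = noise / max(noise.std(), 1e-12)
    perturbed = {}
    for code in (ANTERIOR, POSTERIOR):
        mask = labels.mask(code)
        if not mask.any():
            perturbed[code] = np.full(labels.shape, np.inf)
            continue
        outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
        inside = ndimage.distance_transform_edt(mask, sampling=spacing)
        signed = outside - inside
        perturbed[code] = signed + amplitude_mm * noise
    out = np.zeros(labels.shape, dtype=np.int16)
    ant, post = perturbed[ANTERIOR], perturbed[POSTERIOR]
    out[(ant < 0) & (ant <= post)] = ANTERIOR
    out[(post < 0) & (post < ant)] = POSTERIOR
    return LabelMap(out, spacing, labels.affine)
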