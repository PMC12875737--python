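"""Session-level features and person-centred standardization.

From each session's image and fused label map the pipeline extracts
lobe volumes, median T1-like intensities per lobe, and a Welch
two-sample t-score contrasting posterior against anterior voxel
intensities (positive when the posterior lobe is hyperintense).  Raw
features are then person-centred: z-scored within each subject across
all of that subject's sessions, isolating within-person change from
absolute gland size and scanner scaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import lobe_volume
from .volumes import ANTERIOR, POSTERIOR, ImageVolume, LabelMap

SESSION_TABLE_COLUMNS = [
    "subject_id",
    "session_id",
    "weeks",
    "phase",
    "vol_anterior_mm3",
    "vol_posterior_mm3",
    "median_int_anterior",
    "median_int_posterior",
]


def median_intensity(image: ImageVolume, labels: LabelMap, label: int) -> float:
    """Median in-mask intensity (even counts: midpoint of central pair)."""
    vals = image.data[labels.mask(label)]
    if vals.size == 0:
        raise ValueError(f"empty mask for label {label}: no voxels to summarise")
    return float(np.median(vals))


def intensity_contrast_t(
    anterior_voxels: np.ndarray,
    posterior_voxels: np.ndarray,
    equal_var: bool = False,
) -> float:
    """Two-sample t-score, posterior minus anterior voxel intensities.

    Welch (unequal variance) by default; ``equal_var=True`` selects the
    pooled-variance statistic.
    """
    a = np.asarray(anterior_voxels, dtype=float).ravel()
    p = np.asarray(posterior_voxels, dtype=float).ravel()
    if a.size < 2 or p.size < 2:
        raise ValueError("need >= 2 voxels in each lobe for a t-score")
    return float(stats.ttest_ind(p, a, equal_var=equal_var).statistic)


def person_center(values: np.ndarray) -> np.ndarray:
    """z-score one subject's series with its own mean and sample SD (n-1).

    A zero-SD series maps to all zeros with a warning; a single
    observation is an error because the sample SD is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("person-centring needs >= 2 observations per subject")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero within-subject SD; z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def add_person_centered_columns(
    table: pd.DataFrame,
    columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Append per-subject z-scored versions of feature columns.

    ``columns`` maps source column -> new z column; defaults to the
    volume and t-score features.
    """
    if columns is None:
        columns = {
            "vol_anterior_mm3": "z_vol_anterior",
            "vol_posterior_mm3": "z_vol_posterior",
        }
        if "tscore_post_vs_ant" in table.columns:
            columns["tscore_post_vs_ant"] = "z_tscore"
    out = table.copy()
    for src, dst in columns.items():
        out[dst] = (
            out.groupby("subject_id", sort=False)[src]
            .transform(lambda s: person_center(s.to_numpy()))
        )
    return out


def extract_session_features(
    image: ImageVolume, fused_labels: LabelMap
) -> dict[str, float]:
    """Volume, median-intensity and contrast features for one session."""
    ant = image.data[fused_labels.mask(ANTERIOR)]
    post = image.data[fused_labels.mask(POSTERIOR)]
    feats = {
        "vol_anterior_mm3": lobe_volume(fused_labels, ANTERIOR),
        "vol_posterior_mm3": lobe_volume(fused_labels, POSTERIOR),
        "median_int_anterior": median_intensity(image, fused_labels, ANTERIOR),
        "median_int_posterior": median_intensity(image, fused_labels, POSTERIOR),
    }
    feats["tscore_post_vs_ant"] = intensity_contrast_t(ant, post)
    return feats


def build_feature_table(
    sessions: list[dict],
    subject_id: str,
) -> pd.DataFrame:
    """Feature rows for one subject's list of (image, fused label) sessions.

    Each session dict needs ``session_id``, ``weeks``, ``phase`` (optional),
    ``image`` and ``fused`` entries.
    """
    rows = []
    for s in sessions:
        row = {
            "subject_id": subject_id,
            "session_id": s["session_id"],
            "weeks": float(s["weeks"]),
            "phase": s.get("phase", ""),
        }
        row.update(extract_session_features(s["image"], s["fused"]))
        rows.append(row)
    return pd.DataFrame(rows)
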