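"""Within-subject registration, label propagation and majority-vote fusion.

The longitudinal segmentation scheme: every other session of a subject
is co-registered to a target session (affine, optionally followed by a
symmetric demons-style deformable stage), its label map is propagated
through the transform with nearest-neighbour interpolation, and a
per-voxel majority vote over the propagated stack (plus, by default,
the target's own native labels) defines the fused pituitary borders.
Fusion trades per-session tracing noise against the ensemble consensus.

Registration optimisation is delegated to SimpleITK (multi-resolution
mean-squares affine search; fast symmetric-forces demons for the
deformable stage); transforms are stored backend-agnostically as a 4x4
affine in mm plus an optional dense displacement field on the fixed
grid, so externally computed transforms can be plugged in, and all
resampling and voting logic is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import ANTERIOR, POSTERIOR, VALID_LABELS, ImageVolume, LabelMap, same_grid


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class SessionTransform:
    """Spatial map from a fixed session's grid into a moving session.

    ``affine`` maps homogeneous mm coordinates of the fixed grid into
    the moving image's mm frame; ``displacement_mm`` (optional, shape
    ``(3, *grid)``) is a dense fixed-grid displacement applied *before*
    the affine, so a fixed-grid point ``p`` lands at
    ``affine @ (p + u(p))`` in the moving frame.  World coordinates are
    voxel index times spacing (axis-aligned grids only).
    """

    fixed_session: str
    moving_session: str
    affine: np.ndarray
    spacing: tuple[float, float, float]
    grid_shape: tuple[int, int, int]
    displacement_mm: np.ndarray | None = None
    inverse_displacement_mm: np.ndarray | None = None
    inverse_consistency_error_mm: float = float("nan")
    status: str = "converged"

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.displacement_mm is not None:
            self.displacement_mm = np.asarray(self.displacement_mm, dtype=np.float64)
            if not np.all(np.isfinite(self.displacement_mm)):
                raise ValueError("displacement field contains non-finite values")

    @classmethod
    def identity(cls, like: ImageVolume | LabelMap, fixed: str = "", moving: str = ""):
        return cls(fixed, moving, np.eye(4), like.spacing, like.shape)

    def save_displacement(self, path) -> None:
        """Write the displacement field (mm) as a 4D NIfTI (x, y, z, 3)."""
        import nibabel as nib

        if self.displacement_mm is None:
            raise ValueError("transform has no displacement field")
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        arr = np.moveaxis(self.displacement_mm, 0, -1).astype(np.float32)
        img = nib.Nifti1Image(arr, aff)
        nib.save(img, str(path))

    @classmethod
    def load_displacement(
        cls, path, fixed: str = "", moving: str = ""
    ) -> "SessionTransform":
        """Read a displacement-field NIfTI written by :meth:`save_displacement`."""
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            fixed, moving, np.eye(4), spacing, arr.shape[1:], displacement_mm=arr
        )

    def moving_points_mm(self) -> np.ndarray:
        """Mapped mm coordinates of every fixed-grid node, shape (3, *grid)."""
        grids = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(self.grid_shape, self.spacing)],
            indexing="ij",
        )
        pts = np.stack(grids)
        if self.displacement_mm is not None:
            pts = pts + self.displacement_mm
        out = np.einsum("ab,b...->a...", self.affine[:3, :3], pts)
        return out + self.affine[:3, 3].reshape(3, 1, 1, 1)

    def inverse_consistency(self) -> float:
        """Mean round-trip displacement (mm) through the stored inverse."""
        if self.displacement_mm is None:
            return 0.0
        if self.inverse_displacement_mm is None:
            return float("nan")
        fwd = self.displacement_mm
        inv = self.inverse_displacement_mm
        idx = [
            (np.stack(np.meshgrid(*[np.arange(n) for n in self.grid_shape], indexing="ij"))[a]
             + fwd[a] / self.spacing[a])
            for a in range(3)
        ]
        roundtrip = np.stack(
            [ndimage.map_coordinates(inv[a], idx, order=1, mode="nearest") for a in range(3)]
        )
        err = np.linalg.norm(fwd + roundtrip, axis=0)
        return float(err.mean())


def _to_sitk(vol: ImageVolume | LabelMap, dtype=np.float32) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.data.astype(dtype), (2, 1, 0)))
    )
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin((0.0, 0.0, 0.0))
    return img


def _field_to_numpy(field: sitk.Image) -> np.ndarray:
    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3) with physical (x,y,z) comps
    return np.stack([np.transpose(arr[..., a], (2, 1, 0)) for a in range(3)])


def _sitk_affine_to_matrix(tx: sitk.AffineTransform) -> np.ndarray:
    m = np.array(tx.GetMatrix()).reshape(3, 3)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    aff = np.eye(4)
    aff[:3, :3] = m
    aff[:3, 3] = c + t - m @ c
    return aff


def register_pair(
    fixed: ImageVolume,
    moving: ImageVolume,
    mode: str = "affine+deformable",
    demons_iterations: int = 150,
    demons_smoothing_mm: float = 0.8,
    presmooth_mm: float = 0.25,
) -> SessionTransform:
    """Estimate the fixed -> moving transform between two sessions.

    ``mode``: ``"affine"`` (multi-resolution mean-squares affine search)
    or ``"affine+deformable"`` (affine followed by a fast symmetric
    forces demons displacement field, Gaussian-regularised).
    """
    if mode not in ("affine", "affine+deformable"):
        raise ValueError(f"unknown registration mode: {mode!r}")
    if not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("fixed and moving images must share voxel spacing")
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share grid shape")

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=200,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    init = sitk.AffineTransform(3)
    init.SetCenter(tuple(0.5 * np.array(fixed.shape) * np.array(fixed.spacing)))
    reg.SetInitialTransform(init, inPlace=False)
    out_tx = reg.Execute(f_img, m_img).Downcast()
    if isinstance(out_tx, sitk.CompositeTransform):
        out_tx = out_tx.GetNthTransform(0).Downcast()
    affine_tx = sitk.AffineTransform(out_tx)
    status = "converged"
    stop = reg.GetOptimizerStopConditionDescription()
    if "Maximum number of iterations" in stop:
        status = "warning:max-iterations"
        warnings.warn(f"affine registration hit iteration cap: {stop}", stacklevel=2)

    affine = _sitk_affine_to_matrix(affine_tx)

    displacement = inverse = None
    icc = 0.0
    if mode == "affine+deformable":
        moving_aff = sitk.Resample(
            m_img, f_img, affine_tx, sitk.sitkLinear, 0.0, sitk.sitkFloat32
        )
        if presmooth_mm > 0:
            f_img = sitk.DiscreteGaussian(f_img, presmooth_mm)
            moving_aff = sitk.DiscreteGaussian(moving_aff, presmooth_mm)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(demons_iterations)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(demons_smoothing_mm)
        field = demons.Execute(f_img, moving_aff)
        displacement = _field_to_numpy(field)
        inv_filter = sitk.InvertDisplacementFieldImageFilter()
        inv_filter.SetMaximumNumberOfIterations(30)
        inv_filter.SetEnforceBoundaryCondition(True)
        inverse = _field_to_numpy(inv_filter.Execute(field))

    tx = SessionTransform(
        fixed_session="",
        moving_session="",
        affine=affine,
        spacing=fixed.spacing,
        grid_shape=fixed.shape,
        displacement_mm=displacement,
        inverse_displacement_mm=inverse,
        status=status,
    )
    tx.inverse_consistency_error_mm = tx.inverse_consistency()
    return tx


def propagate_labels(transform: SessionTransform, labels: LabelMap) -> LabelMap:
    """Carry a moving-session label map onto the fixed grid (nearest-neighbour)."""
    if labels.shape != transform.grid_shape or not np.allclose(
        labels.spacing, transform.spacing
    ):
        raise ValueError("label map grid does not match the transform's grid")
    pts = transform.moving_points_mm()
    idx = [pts[a] / transform.spacing[a] for a in range(3)]
    out = ndimage.map_coordinates(labels.data, idx, order=0, mode="constant", cval=0)
    return LabelMap(out.astype(np.int16), transform.spacing, labels.affine)


# ---------------------------------------------------------------------------
# voting and agreement metrics
# ---------------------------------------------------------------------------


@dataclass
class FusionResult:
    fused: LabelMap
    vote_counts: np.ndarray  # (n_labels, *grid), summing to n per voxel
    n: int
    tie_voxels: int
    volumes_mm3: dict[int, float]
    dice_vs_native: dict[int, float]


def majority_vote(label_stack: list[LabelMap], native: LabelMap) -> FusionResult:
    """Per-voxel plurality vote over a stack of aligned label maps.

    Exact ties go to the native (target-session) label when it is among
    the tied leaders, otherwise to the lowest tied label code.  The
    caller decides whether ``native`` itself is part of the stack.
    """
    if len(label_stack) == 0:
        raise ValueError("empty label stack")
    for lm in label_stack:
        if not same_grid(lm, native):
            raise ValueError("all label maps must share the native grid")
    n = len(label_stack)
    counts = np.zeros((len(VALID_LABELS),) + native.shape, dtype=np.int32)
    for lm in label_stack:
        for code in VALID_LABELS:
            counts[code] += lm.data == code
    max_votes = counts.max(axis=0)
    n_at_max = (counts == max_votes[None]).sum(axis=0)
    fused = counts.argmax(axis=0).astype(np.int16)
    tie = n_at_max > 1
    native_counts = np.take_along_axis(
        counts, native.data[None].astype(np.int64), axis=0
    )[0]
    native_wins = tie & (native_counts == max_votes)
    fused[native_wins] = native.data[native_wins]
    fused_map = LabelMap(fused, native.spacing, native.affine)
    return FusionResult(
        fused=fused_map,
        vote_counts=counts,
        n=n,
        tie_voxels=int(tie.sum()),
        volumes_mm3={c: lobe_volume(fused_map, c) for c in (ANTERIOR, POSTERIOR)},
        dice_vs_native={c: dice(fused_map, native, c) for c in (ANTERIOR, POSTERIOR)},
    )


def dice(a: LabelMap, b: LabelMap, label: int) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) for one label; 1.0 when both empty."""
    ma, mb = a.mask(label), b.mask(label)
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def lobe_volume(
    labels: LabelMap, label: int, voxel_size: tuple[float, float, float] | None = None
) -> float:
    """Lobe volume in mm^3: voxel count times voxel volume."""
    spacing = labels.spacing if voxel_size is None else voxel_size
    return float(labels.mask(label).sum()) * float(np.prod(spacing))


def fuse_target_session(
    images: list[ImageVolume],
    labels: list[LabelMap],
    target: int,
    mode: str = "affine+deformable",
    include_native: bool = True,
) -> FusionResult:
    """Full ensemble segmentation of one target session.

    Registers every other session to the target, propagates its labels
    and majority-votes the stack (native labels included by default).
    """
    if len(images) != len(labels) or len(images) < 2:
        raise ValueError("need matched image/label lists with >= 2 sessions")
    native = labels[target]
    stack = [native] if include_native else []
    for j, (img, lab) in enumerate(zip(images, labels)):
        if j == target:
            continue
        tx = register_pair(images[target], img, mode=mode)
        stack.append(propagate_labels(tx, lab))
    return majority_vote(stack, native)
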