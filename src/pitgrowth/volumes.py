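"""Voxel containers and NIfTI I/O.

Two thin carriers are used throughout the pipeline: :class:`ImageVolume`
for T1-like scalar intensities and :class:`LabelMap` for integer lobe
labels (0 background, 1 anterior pituitary, 2 posterior pituitary).
Both hold a 3D array in (x, y, z) index order plus isotropic-or-not
voxel spacing in mm and a NIfTI-style affine.  Only axis-aligned
(diagonal, positive) affines are supported; that is all the phantom
generator produces and all the registration stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

ANTERIOR = 1
POSTERIOR = 2
BACKGROUND = 0
VALID_LABELS = (BACKGROUND, ANTERIOR, POSTERIOR)


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """3D scalar image with voxel spacing (mm) and affine orientation."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
            affine=np.asarray(img.affine),
        )


@dataclass
class LabelMap:
    """3D integer label map aligned to an :class:`ImageVolume` grid.

    Codes: 0 background, 1 anterior lobe, 2 posterior lobe.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label data must be integer-valued")
            self.data = rounded.astype(np.int16)
        else:
            self.data = self.data.astype(np.int16)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D array, got shape {self.data.shape}")
        bad = np.setdiff1d(np.unique(self.data), VALID_LABELS)
        if bad.size:
            raise ValueError(f"label codes outside {VALID_LABELS}: {bad.tolist()}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "LabelMap":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.dataobj),
            spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
            affine=np.asarray(img.affine),
        )


def same_grid(a, b, atol: float = 1e-6) -> bool:
    """True when two volumes share shape, spacing and affine."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.affine, b.affine, atol=atol)
    )
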