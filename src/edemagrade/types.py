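"""Shared in-memory containers for volumes, masks and subjects.

Volumes follow BraTS conventions: four co-registered, skull-stripped MRI
weights (T1, T1Gd, T2, FLAIR) on a common 1 mm isotropic grid, and an
integer tumor mask with labels 1 (necrotic core), 2 (peritumoral edema)
and 4 (enhancing tumor).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

MODALITIES = ("T1", "T1Gd", "T2", "FLAIR")

#: BraTS tumor-subregion labels
LABEL_NECROTIC = 1
LABEL_EDEMA = 2
LABEL_ENHANCING = 4
VALID_LABELS = frozenset({0, LABEL_NECROTIC, LABEL_EDEMA, LABEL_ENHANCING})


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with voxel spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, img.affine)


@dataclass
class SegMask:
    """Integer label volume sharing the grid of its VolumeImage."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int16)
        labels = set(np.unique(self.data).tolist())
        if not labels <= VALID_LABELS:
            raise ValueError(f"mask labels {labels - VALID_LABELS} outside {sorted(VALID_LABELS)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.int16), self.affine)

    @classmethod
    def from_nifti(cls, path) -> "SegMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj).astype(np.int16), spacing, img.affine)


@dataclass
class SubjectRecord:
    """One synthetic or real subject: four MRI weights, a mask, a grade."""

    subject_id: str
    modalities: dict[str, VolumeImage]
    mask: SegMask
    grade: str  # "LGG" or "HGG"

    def __post_init__(self) -> None:
        if self.grade not in ("LGG", "HGG"):
            raise ValueError(f"grade must be LGG or HGG, got {self.grade!r}")
        missing = set(MODALITIES) - set(self.modalities)
        if missing:
            raise ValueError(f"missing modalities: {sorted(missing)}")
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if len(set(shapes.values())) != 1 or next(iter(shapes.values())) != self.mask.shape:
            raise ValueError(f"modalities/mask grids differ: {shapes}, mask {self.mask.shape}")
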