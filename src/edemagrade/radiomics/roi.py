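"""ROI extraction and fixed-bin-width gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import SegMask, VolumeImage

__all__ = ["ROISpec", "ROIData", "DiscretizedROI", "extract_roi", "discretize"]


@dataclass(frozen=True)
class ROISpec:
    """Which mask label defines the ROI (edema, label 2, by default)."""

    label: int = 2
    min_voxels: int = 8

    def __post_init__(self) -> None:
        if self.label not in (1, 2, 4):
            raise ValueError(f"label must be one of 1, 2, 4; got {self.label}")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


class EmptyROIError(ValueError):
    """Raised when the requested label is absent or below min_voxels."""


@dataclass
class ROIData:
    """A masked sub-volume: bounding-box intensities + in-ROI mask."""

    values: np.ndarray        # bounding-box sub-volume of intensities
    inroi: np.ndarray         # boolean mask, same shape as values
    bbox: tuple[slice, slice, slice]
    spacing: tuple[float, float, float]

    @property
    def count(self) -> int:
        return int(self.inroi.sum())

    @property
    def roi_values(self) -> np.ndarray:
        """1D intensities of the ROI voxels."""
        return self.values[self.inroi]


@dataclass
class DiscretizedROI:
    """Gray levels 1..Ng on the ROI bounding box (0 = outside ROI)."""

    levels: np.ndarray  # int array, 0 outside ROI
    Ng: int
    bin_width: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def inroi(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(self.inroi.sum())


def extract_roi(volume: VolumeImage, mask: SegMask, spec: ROISpec = ROISpec()) -> ROIData:
    """Extract the labelled ROI and its bounding box from a volume."""
    if volume.shape != mask.shape:
        raise ValueError(f"volume/mask grids differ: {volume.shape} vs {mask.shape}")
    sel = mask.data == spec.label
    n = int(sel.sum())
    if n == 0:
        raise EmptyROIError(f"label {spec.label} absent from mask")
    if n < spec.min_voxels:
        raise EmptyROIError(f"label {spec.label} has {n} voxels < min_voxels={spec.min_voxels}")
    idx = np.argwhere(sel)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return ROIData(
        values=np.asarray(volume.data[bbox], dtype=np.float64),
        inroi=sel[bbox],
        bbox=bbox,
        spacing=volume.spacing,
    )


def discretize(roi: ROIData | np.ndarray, bin_width: float = 25.0,
               inroi: np.ndarray | None = None,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> DiscretizedROI:
    """Fixed-bin-width discretization anchored at the ROI minimum.

    level(v) = floor((v - min_roi) / bin_width) + 1, so intensity shifts
    leave the levels unchanged.  Accepts either an :class:`ROIData` or a
    raw array plus ``inroi`` mask.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(roi, ROIData):
        values, sel, spacing = roi.values, roi.inroi, roi.spacing
    else:
        values = np.asarray(roi, dtype=np.float64)
        sel = np.ones(values.shape, dtype=bool) if inroi is None else np.asarray(inroi, dtype=bool)
    if not sel.any():
        raise EmptyROIError("no ROI voxels to discretize")
    vmin = values[sel].min()
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[sel] = np.floor((values[sel] - vmin) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(levels=levels, Ng=int(levels.max()), bin_width=float(bin_width),
                          spacing=tuple(spacing))
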