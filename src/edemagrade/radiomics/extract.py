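"""Full 851-feature radiomic extraction from the edema ROI of a volume.

Composition: 14 shape features (mask-only) + 93 intensity/texture
features on the original image + 93 on each of the 8 stationary-wavelet
sub-bands (744), all on the same ROI voxels, with fixed-bin-width
discretization anchored at each image type's ROI minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..types import SegMask, SubjectRecord, VolumeImage
from .firstorder import firstorder_features
from .registry import N_TOTAL, full_feature_names
from .roi import ROIData, ROISpec, discretize, extract_roi
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .wavelet import wavelet_subbands

__all__ = ["RadiomicsConfig", "extract_all", "extract_table"]


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings: ROI label, bin width, wavelet filter."""

    roi: ROISpec = ROISpec(label=2, min_voxels=8)
    bin_width: float = 25.0
    wavelet: str = "coif1"
    gldm_alpha: int = 0
    include_wavelet: bool = True

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def _intensity_block(
    image_type: str,
    values: np.ndarray,
    inroi: np.ndarray,
    cfg: RadiomicsConfig,
    spacing: tuple[float, float, float],
) -> dict[str, float]:
    """93 first-order + texture features for one image type."""
    d = discretize(values, cfg.bin_width, inroi=inroi, spacing=spacing)
    voxel_volume = float(np.prod(spacing))
    block: dict[str, float] = {}
    family_values = {
        "firstorder": firstorder_features(values[inroi], cfg.bin_width, voxel_volume),
        "glcm": glcm_features(d),
        "gldm": gldm_features(d, cfg.gldm_alpha),
        "glrlm": glrlm_features(d),
        "glszm": glszm_features(d),
        "ngtdm": ngtdm_features(d),
    }
    for family, feats in family_values.items():
        for name, value in feats.items():
            block[f"{image_type}_{family}_{name}"] = value
    return block


def extract_all(
    volume: VolumeImage,
    mask: SegMask,
    cfg: RadiomicsConfig = RadiomicsConfig(),
) -> dict[str, float]:
    """Extract the full, ordered 851-feature vector from one volume.

    Raises on non-finite results, naming the offending feature.
    """
    roi: ROIData = extract_roi(volume, mask, cfg.roi)
    feats: dict[str, float] = {}
    for name, value in shape_features(roi.inroi, roi.spacing).items():
        feats[f"original_shape_{name}"] = value
    feats.update(_intensity_block("original", roi.values, roi.inroi, cfg, roi.spacing))
    if cfg.include_wavelet:
        for band_name, band in wavelet_subbands(roi.values, cfg.wavelet).items():
            feats.update(
                _intensity_block(f"wavelet-{band_name}", band, roi.inroi, cfg, roi.spacing)
            )
        expected = full_feature_names()
        assert list(feats) == expected and len(feats) == N_TOTAL
    for name, value in feats.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite feature value for {name!r}: {value}")
    return feats


def extract_table(
    records: list[SubjectRecord],
    volume_getter,
    image_type: str,
    cfg: RadiomicsConfig = RadiomicsConfig(),
) -> pd.DataFrame:
    """Per-subject feature rows for one image type.

    ``volume_getter(record) -> VolumeImage`` selects the image (an
    original weight or a fused volume).  Returns a wide DataFrame with
    subject_id, image_type, grade and one column per feature.
    """
    rows = []
    for rec in records:
        feats = extract_all(volume_getter(rec), rec.mask, cfg)
        row = {"subject_id": rec.subject_id, "image_type": image_type, "grade": rec.grade}
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)
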