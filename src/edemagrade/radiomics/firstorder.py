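"""First-order intensity statistics of an ROI (18 values)."""

from __future__ import annotations

import numpy as np

from .registry import FIRSTORDER_FEATURES

__all__ = ["firstorder_features"]


def _binned_probabilities(values: np.ndarray, bin_width: float) -> np.ndarray:
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64)
    counts = np.bincount(levels)
    return counts[counts > 0] / values.size


def firstorder_features(
    values: np.ndarray,
    bin_width: float = 25.0,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """The standard 18 first-order statistics.

    Entropy and Uniformity use the fixed-bin-width histogram (same
    discretization as the texture families); Skewness is 0 and Kurtosis
    0 for constant ROIs (moment ratios are undefined there).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty ROI")
    n = v.size
    mean = v.mean()
    centered = v - mean
    m2 = float((centered**2).mean())
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    p = _binned_probabilities(v, bin_width)

    if m2 > 0:
        skewness = float((centered**3).mean() / m2**1.5)
        kurtosis = float((centered**4).mean() / m2**2)
    else:
        skewness = 0.0
        kurtosis = 0.0

    energy = float((v**2).sum())
    out = {
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Variance": m2,
        "Uniformity": float((p**2).sum()),
    }
    return {name: out[name] for name in FIRSTORDER_FEATURES}
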