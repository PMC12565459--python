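"""Fused-image quality metrics: entropy, STD, PSNR, SSIM.

All metrics assume an 8-bit-like working range [0, 255], matching the
fusion stage's intensity harmonization.  PSNR and SSIM are directional:
they compare a fused image against one of its two source weights, and
reports store which source served as reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "QualityReport",
    "entropy",
    "std",
    "psnr",
    "ssim",
    "compute_quality",
    "normalize_metrics",
    "PSNR_INF_SENTINEL",
]

#: Sentinel reported for PSNR of identical images (MSE = 0).
PSNR_INF_SENTINEL = math.inf

WORKING_RANGE = (0.0, 255.0)
N_BINS = 256


def _as_finite(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def entropy(image) -> float:
    """Shannon entropy (bits) of the 256-bin histogram over [0, 255]."""
    arr = _as_finite(image)
    counts, _ = np.histogram(arr, bins=N_BINS, range=WORKING_RANGE)
    p = counts[counts > 0] / arr.size
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids -0.0


def std(image) -> float:
    """Population standard deviation of the intensities."""
    return float(np.std(_as_finite(image)))


def psnr(reference, test, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images -> inf sentinel."""
    ref = _as_finite(reference)
    tst = _as_finite(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return PSNR_INF_SENTINEL
    return float(10.0 * math.log10(peak**2 / mse))


def ssim(reference, test, data_range: float = 255.0, gaussian: bool = False) -> float:
    """Mean local structural similarity index in [-1, 1].

    Standard constants C1 = (0.01*255)^2, C2 = (0.03*255)^2 with a 7-wide
    uniform local window by default (``gaussian=True`` switches to the
    Gaussian-weighted 11-wide window).
    """
    ref = _as_finite(reference)
    tst = _as_finite(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    return float(
        structural_similarity(
            ref, tst, data_range=data_range, gaussian_weights=gaussian,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


@dataclass
class QualityReport:
    """Quality metrics of one fused image against its two sources."""

    entropy: float
    std: float
    psnr: dict[str, float]  # reference name -> dB
    ssim: dict[str, float]  # reference name -> value
    normalized: dict[str, float] = field(default_factory=dict)

    def as_rows(self, subject_id: str, fused_type: str) -> list[dict]:
        rows = [
            {"subject_id": subject_id, "fused_type": fused_type, "metric": "entropy",
             "reference": "", "value": self.entropy},
            {"subject_id": subject_id, "fused_type": fused_type, "metric": "std",
             "reference": "", "value": self.std},
        ]
        for ref, v in self.psnr.items():
            rows.append({"subject_id": subject_id, "fused_type": fused_type,
                         "metric": "psnr", "reference": ref, "value": v})
        for ref, v in self.ssim.items():
            rows.append({"subject_id": subject_id, "fused_type": fused_type,
                         "metric": "ssim", "reference": ref, "value": v})
        return rows


def compute_quality(fused, sources: dict[str, np.ndarray]) -> QualityReport:
    """Full quality report: PSNR/SSIM against each source weight.

    ``sources`` maps weight name -> array on the same grid as ``fused``.
    """
    fused_arr = _as_finite(fused)
    return QualityReport(
        entropy=entropy(fused_arr),
        std=std(fused_arr),
        psnr={name: psnr(src, fused_arr) for name, src in sources.items()},
        ssim={name: ssim(src, fused_arr) for name, src in sources.items()},
    )


def normalize_metrics(metric_table: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Min-max normalize each metric across fused types to [0, 1].

    ``metric_table`` maps fused-type -> {metric name -> value}.  A metric
    constant across all fused types normalizes to 0 for every type (with
    a warning), mirroring the degenerate min-max rule used elsewhere.
    """
    if len(metric_table) < 2:
        raise ValueError("need at least two fused types to normalize across")
    types = list(metric_table)
    metrics = sorted({m for row in metric_table.values() for m in row})
    out: dict[str, dict[str, float]] = {t: {} for t in types}
    for m in metrics:
        vals = np.array([metric_table[t][m] for t in types], dtype=np.float64)
        finite = vals[np.isfinite(vals)]
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 0.0
        if hi == lo:
            warnings.warn(f"metric {m!r} constant across fused types; normalized to 0")
            for t in types:
                out[t][m] = 0.0
            continue
        for t, v in zip(types, vals):
            out[t][m] = 1.0 if np.isposinf(v) else float((v - lo) / (hi - lo))
    return out
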