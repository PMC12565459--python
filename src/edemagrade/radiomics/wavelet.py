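"""One-level 3D stationary wavelet decomposition into 8 sub-bands.

The undecimated (stationary) transform keeps every sub-band at the input
shape, so the ROI mask applies unchanged.  Default filter is Coiflet-1
with one decomposition level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

from .registry import WAVELET_BANDS

__all__ = ["wavelet_subbands"]


def wavelet_subbands(volume: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Decompose a volume into the 8 {L,H}^3 stationary sub-bands.

    Axes shorter than the filter support are edge-padded first (with a
    warning) and the result cropped back, so sub-band shapes always equal
    the input shape.  Keys are LLL..HHH with the letter order following
    the array axes.
    """
    arr = np.asarray(volume, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    filt_len = pywt.Wavelet(wavelet).dec_len
    pad = []
    for size in arr.shape:
        target = max(size, filt_len)
        target += target % 2  # SWT level 1 needs even dims
        pad.append((0, target - size))
    if any(p[1] > 0 for p in pad):
        if any(size < filt_len for size in arr.shape):
            warnings.warn(
                f"ROI bounding box {arr.shape} shorter than the {wavelet} filter; "
                "edge-padding before the stationary wavelet transform"
            )
        arr = np.pad(arr, pad, mode="edge")

    coeffs = pywt.swtn(arr, wavelet, level=1, start_level=0)[0]
    out: dict[str, np.ndarray] = {}
    for key, band in coeffs.items():
        name = key.upper().replace("A", "L").replace("D", "H")
        out[name] = band[: volume.shape[0], : volume.shape[1], : volume.shape[2]]
    return {b: out[b] for b in WAVELET_BANDS}
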