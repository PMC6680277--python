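"""Fixed preprocessing chain for reconstructed 32-bit μCT volumes.

The chain mirrors how FFPE-block scans are conditioned before gray-value
calibration: a 3D median filter to suppress shot noise, a per-slice 2D
unsharp mask to restore edge contrast, and a linear windowing of the float
gray values onto the unsigned 16-bit range. The default window (−50, 100)
brackets the attenuation values of air, paraffin wax and soft tissue in
reconstructed FFPE data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume_io import Volume

__all__ = [
    "WindowSpec",
    "median_filter_3d",
    "unsharp_mask_2d",
    "window_and_quantize",
    "preprocess",
]


@dataclass(frozen=True)
class WindowSpec:
    """Linear gray-value window ``(lo, hi)``; values outside are clamped."""

    lo: float = -50.0
    hi: float = 100.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window lo must be < hi, got ({self.lo}, {self.hi})")


def median_filter_3d(volume: Volume, radius: int = 1) -> Volume:
    """3D median filter with a cubic window of half-width ``radius``.

    Each voxel is replaced by the median of its ``(2*radius+1)**3``
    neighbourhood; borders are handled by edge replication so no new gray
    values appear near the block edges.
    """
    if volume.data.dtype.kind != "f":
        raise ValueError("median_filter_3d expects a float-valued volume")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    size = 2 * int(radius) + 1
    out = ndi.median_filter(volume.data, size=size, mode="nearest")
    return volume.with_data(out.astype(volume.data.dtype))


def unsharp_mask_2d(volume: Volume, sigma_px: float = 2.0, weight: float = 0.6) -> Volume:
    """Per-slice unsharp mask: ``(I - w * G_sigma(I)) / (1 - w)``.

    Applied independently to every z-slice (the reconstructed CT slices).
    The normalisation by ``1 - w`` keeps constant regions unchanged, so wax
    and air plateaus retain their mean gray value.
    """
    if volume.data.dtype.kind != "f":
        raise ValueError("unsharp_mask_2d expects a float-valued volume")
    if not 0.0 < weight < 1.0:
        raise ValueError(f"weight must be in (0, 1), got {weight}")
    if not sigma_px > 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px}")
    data = volume.data.astype(np.float64, copy=False)
    # Gaussian blur over (y, x) only; slices are independent.
    blurred = ndi.gaussian_filter(data, sigma=(0.0, sigma_px, sigma_px), mode="nearest")
    out = (data - weight * blurred) / (1.0 - weight)
    return volume.with_data(out.astype(volume.data.dtype))


def window_and_quantize(volume: Volume, window: WindowSpec = WindowSpec()) -> Volume:
    """Linearly map ``[lo, hi]`` onto ``[0, 65535]`` and convert to uint16.

    Values at or below ``lo`` map to 0, at or above ``hi`` to 65535;
    in-between values map linearly and are rounded half-up. The result is
    tagged ``calibration_state='preprocessed'``.
    """
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume contains non-finite values; cannot window")
    lo, hi = float(window.lo), float(window.hi)
    scaled = (volume.data.astype(np.float64) - lo) / (hi - lo) * 65535.0
    quantized = np.floor(scaled + 0.5)  # round half up
    quantized = np.clip(quantized, 0, 65535).astype(np.uint16)
    return volume.with_data(quantized, calibration_state="preprocessed")


def preprocess(
    volume: Volume,
    median_radius: int = 1,
    unsharp_sigma_px: float = 2.0,
    unsharp_weight: float = 0.6,
    window: WindowSpec = WindowSpec(),
) -> Volume:
    """Full chain: 3D median -> per-slice unsharp mask -> window to 16 bit."""
    out = median_filter_3d(volume, radius=median_radius)
    out = unsharp_mask_2d(out, sigma_px=unsharp_sigma_px, weight=unsharp_weight)
    return window_and_quantize(out, window=window)
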