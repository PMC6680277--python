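"""Phantom-based gray-value calibration and scanner-stability reporting.

Unstained FFPE scans contain two reference materials in every field of view:
air and paraffin wax. Their mean gray values ``I_air`` and ``I_wax`` define a
per-scan contrast factor

    contrast factor = (I_wax - I_air) / I_wax

and a sample is aligned to a dedicated wax phantom scan through

    calibration factor = contrast_factor(phantom) / contrast_factor(sample).

The sample volume is multiplied by the calibration factor and then linearly
offset so that the mean gray value of air becomes 0 (the wax standard plays
the role water plays in the clinical Hounsfield scale). Calibrated volumes
therefore have non-negative gray values with air at 0, which makes gray
values comparable across scans, sessions and scanners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import signal

from .volume_io import Volume

__all__ = [
    "MaterialLevels",
    "CalibrationResult",
    "MaterialStability",
    "StabilityReport",
    "estimate_material_levels",
    "contrast_factor",
    "calibration_factor",
    "build_calibration",
    "apply_calibration",
    "stability_report",
]


@dataclass(frozen=True)
class MaterialLevels:
    """Mean gray values of the two reference materials in one scan."""

    i_air: float
    i_wax: float
    source_slice_index: int = -1

    def __post_init__(self) -> None:
        if not self.i_wax > self.i_air:
            raise ValueError(
                f"wax must attenuate more than air: i_wax={self.i_wax} <= i_air={self.i_air}"
            )


@dataclass(frozen=True)
class CalibrationResult:
    """Everything needed to map a sample scan onto the phantom's gray scale."""

    phantom_levels: MaterialLevels
    sample_levels: MaterialLevels
    contrast_factor_phantom: float
    contrast_factor_sample: float
    calibration_factor: float
    air_offset: float  # gray value subtracted after scaling so that air -> 0

    def to_dict(self) -> dict:
        return {
            "phantom": {"i_air": self.phantom_levels.i_air, "i_wax": self.phantom_levels.i_wax},
            "sample": {"i_air": self.sample_levels.i_air, "i_wax": self.sample_levels.i_wax},
            "contrast_factor_phantom": self.contrast_factor_phantom,
            "contrast_factor_sample": self.contrast_factor_sample,
            "calibration_factor": self.calibration_factor,
            "air_offset": self.air_offset,
        }


def estimate_material_levels(
    volume: Volume,
    method: str = "histogram_peaks",
    masks: dict[str, np.ndarray] | None = None,
    slice_index: int | None = None,
) -> MaterialLevels:
    """Estimate the mean gray values of air and wax in one scan.

    ``histogram_peaks`` analyses the histogram of the central z-slice
    (relative to the rotation axis): the histogram of an FFPE scan shows the
    material populations air < wax (< tissue) as modes. Peaks are found on a
    smoothed histogram; air is the lowest-gray mode and wax the next one.
    The reported level per material is the mean gray value of the voxels
    falling in that mode's basin (split at midpoints between peaks).

    ``roi_masks`` bypasses the histogram and returns exact means over caller-
    supplied boolean regions ``masks={'air': ..., 'wax': ...}`` (full-volume
    masks).
    """
    if method == "roi_masks":
        if not masks or "air" not in masks or "wax" not in masks:
            raise ValueError("roi_masks method needs masks={'air': ..., 'wax': ...}")
        for name in ("air", "wax"):
            if not np.any(masks[name]):
                raise ValueError(f"empty {name} mask")
        return MaterialLevels(
            i_air=float(volume.data[masks["air"]].mean()),
            i_wax=float(volume.data[masks["wax"]].mean()),
            source_slice_index=-1,
        )
    if method != "histogram_peaks":
        raise ValueError(f"unknown method {method!r}")

    k = volume.meta.shape[0] // 2 if slice_index is None else int(slice_index)
    sl = volume.data[k].astype(np.float64)
    lo, hi = float(sl.min()), float(sl.max())
    if hi <= lo:
        raise ValueError("fewer than two material modes: slice is constant")
    nbins = 256
    counts, edges = np.histogram(sl, bins=nbins, range=(lo, hi))
    smooth = ndi.gaussian_filter1d(counts.astype(np.float64), sigma=2.0, mode="nearest")
    peaks, _ = signal.find_peaks(smooth, prominence=0.01 * smooth.max())
    # Peaks flush against the histogram ends are missed by find_peaks; check ends.
    for end in (0, nbins - 1):
        inner = smooth[1] if end == 0 else smooth[-2]
        if smooth[end] > inner and smooth[end] > 0.01 * smooth.max():
            peaks = np.sort(np.append(peaks, end))
    if len(peaks) < 2:
        raise ValueError("fewer than two material modes detected in central-slice histogram")
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak_grays = centers[np.sort(peaks)]
    # air = lowest mode, wax = next; tissue (if present) lies above wax.
    boundaries = (peak_grays[:-1] + peak_grays[1:]) / 2.0
    air_sel = sl <= boundaries[0]
    wax_hi = boundaries[1] if len(boundaries) > 1 else np.inf
    wax_sel = (sl > boundaries[0]) & (sl <= wax_hi)
    if not air_sel.any() or not wax_sel.any():
        raise ValueError("mode basins are empty; cannot estimate material levels")
    return MaterialLevels(
        i_air=float(sl[air_sel].mean()),
        i_wax=float(sl[wax_sel].mean()),
        source_slice_index=k,
    )


def contrast_factor(levels: MaterialLevels | tuple[float, float]) -> float:
    """Normalized wax/air gray-value contrast ``(I_wax - I_air) / I_wax``."""
    if isinstance(levels, MaterialLevels):
        i_air, i_wax = levels.i_air, levels.i_wax
    else:
        i_air, i_wax = float(levels[0]), float(levels[1])
    if i_wax == 0:
        raise ValueError("contrast factor undefined for i_wax = 0")
    if i_wax <= i_air:
        warnings.warn(
            f"non-physical material ordering i_wax={i_wax} <= i_air={i_air}",
            stacklevel=2,
        )
    return (i_wax - i_air) / i_wax


def calibration_factor(cf_phantom: float, cf_sample: float) -> float:
    """Multiplicative factor aligning a sample's wax/air contrast to the phantom's."""
    if cf_sample == 0:
        raise ValueError("calibration factor undefined for zero sample contrast factor")
    return cf_phantom / cf_sample


def build_calibration(
    phantom_levels: MaterialLevels,
    sample_levels: MaterialLevels,
) -> CalibrationResult:
    """Assemble a :class:`CalibrationResult` from measured material levels."""
    cf_p = contrast_factor(phantom_levels)
    cf_s = contrast_factor(sample_levels)
    k = calibration_factor(cf_p, cf_s)
    if not k > 0:
        raise ValueError(f"calibration factor must be positive, got {k}")
    return CalibrationResult(
        phantom_levels=phantom_levels,
        sample_levels=sample_levels,
        contrast_factor_phantom=cf_p,
        contrast_factor_sample=cf_s,
        calibration_factor=k,
        air_offset=k * sample_levels.i_air,
    )


def apply_calibration(volume: Volume, result: CalibrationResult) -> Volume:
    """Scale by the calibration factor and offset so that air maps to mean 0.

    ``output = input * calibration_factor - air_offset`` with
    ``air_offset = calibration_factor * sample I_air``. Integer (uint16)
    volumes are rounded half-up and clipped to [0, 65535] — stored
    calibrated gray values are always non-negative, with air at 0. Float
    volumes keep sub-zero noise excursions so the air population stays
    symmetric about an exact zero mean; clipping there is storage's job
    (see :func:`xrh.volume_io.write_volume`).
    """
    if volume.meta.calibration_state == "calibrated":
        raise ValueError("volume is already calibrated")
    k = result.calibration_factor
    out = volume.data.astype(np.float64) * k - result.air_offset
    if volume.data.dtype == np.uint16:
        out = np.clip(np.floor(out + 0.5), 0, 65535).astype(np.uint16)
    else:
        out = out.astype(volume.data.dtype)
    return volume.with_data(out, calibration_state="calibrated")


# ---------------------------------------------------------------------------
# multi-scan stability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialStability:
    """Across-specimen statistics of one material's mean gray value."""

    specimen_means: tuple[float, ...]
    grand_mean: float
    sem: float
    max_pct_fluctuation: float


@dataclass(frozen=True)
class StabilityReport:
    materials: dict[str, MaterialStability] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            name: {
                "specimen_means": list(stat.specimen_means),
                "grand_mean": stat.grand_mean,
                "sem": stat.sem,
                "max_pct_fluctuation": stat.max_pct_fluctuation,
            }
            for name, stat in self.materials.items()
        }


def _material_stability(means: np.ndarray) -> MaterialStability:
    grand = float(means.mean())
    sem = float(means.std(ddof=1) / np.sqrt(len(means)))
    fluct = float(np.abs(means - grand).max() / grand * 100.0)
    return MaterialStability(tuple(float(m) for m in means), grand, sem, fluct)


def stability_report(
    volumes: list[Volume],
    wax_masks: list[np.ndarray] | None = None,
    tissue_masks: list[np.ndarray] | None = None,
) -> StabilityReport:
    """Across-specimen gray-value stability of calibrated scans.

    For each material, per-specimen mean gray values over the given masks are
    summarised by their grand mean, SEM (sd of specimen means / sqrt(n)) and
    maximum percent fluctuation ``max |mean_i - grand| / grand * 100``. A
    stable, well-calibrated protocol keeps the wax fluctuation below ~1% and
    tissue below ~2%.
    """
    if len(volumes) < 2:
        raise ValueError("stability report needs at least 2 calibrated volumes")
    for v in volumes:
        if v.meta.calibration_state != "calibrated":
            raise ValueError("stability report requires calibrated volumes")
    materials: dict[str, MaterialStability] = {}
    for name, mask_list in (("wax", wax_masks), ("tissue", tissue_masks)):
        if mask_list is None:
            continue
        if len(mask_list) != len(volumes):
            raise ValueError(f"need one {name} mask per volume")
        means = np.array(
            [float(v.data[m].mean()) for v, m in zip(volumes, mask_list)], dtype=np.float64
        )
        materials[name] = _material_stability(means)
    if not materials:
        raise ValueError("no material masks provided")
    return StabilityReport(materials)
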