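"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct definitions, exhaustive
enumeration — and shares nothing with the package implementation beyond the
declared digital-geometry conventions.
"""

from __future__ import annotations

import numpy as np


def brute_median_3d(data: np.ndarray, radius: int) -> np.ndarray:
    """Per-voxel sorted-neighbourhood median with edge replication."""
    pad = np.pad(data, radius, mode="edge")
    out = np.empty_like(data)
    w = 2 * radius + 1
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                block = pad[z : z + w, y : y + w, x : x + w].ravel()
                out[z, y, x] = np.sort(block)[block.size // 2]
    return out


def naive_gaussian_blur_2d(image: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Separable Gaussian by explicit convolution with edge replication."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()

    def conv1d(arr: np.ndarray, axis: int) -> np.ndarray:
        padded = np.pad(
            arr, [(radius, radius) if a == axis else (0, 0) for a in range(arr.ndim)],
            mode="edge",
        )
        out = np.zeros_like(arr, dtype=np.float64)
        for i, kv in enumerate(kernel):
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(i, i + arr.shape[axis])
            out += kv * padded[tuple(sl)]
        return out

    return conv1d(conv1d(image.astype(np.float64), 0), 1)


def brute_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive maximal-sphere local thickness (voxel units).

    For every foreground centre c the maximal ball radius is the direct
    minimum distance to any background voxel (out-of-bounds counts as
    background, realised by a one-voxel ring — the nearest outside point to
    any inside voxel always lies in that ring). A voxel p is covered by c's
    ball iff |p - c| < R(c); its thickness is the largest covering ball
    diameter 2 * (R(c) - 0.5).
    """
    pad = np.pad(mask, 1, constant_values=False)
    fg = np.argwhere(pad)
    bg = np.argwhere(~pad)
    if fg.size == 0:
        return np.zeros(mask.shape)
    d2 = ((fg[:, None, :] - bg[None, :, :]) ** 2).sum(-1)
    radius = np.sqrt(d2.min(axis=1))
    pd2 = ((fg[:, None, :] - fg[None, :, :]) ** 2).sum(-1)
    covered = pd2 < radius[None, :] ** 2
    diam = 2.0 * (radius - 0.5)
    thick = np.where(covered, diam[None, :], 0.0).max(axis=1)
    out = np.zeros(pad.shape)
    out[tuple(fg.T)] = thick
    return out[1:-1, 1:-1, 1:-1]


def recompute_calibration(
    sample_data: np.ndarray,
    i_air_phantom: float,
    i_wax_phantom: float,
    i_air_sample: float,
    i_wax_sample: float,
) -> np.ndarray:
    """Direct recomputation of the calibrated volume from the two equations."""
    cf_p = (i_wax_phantom - i_air_phantom) / i_wax_phantom
    cf_s = (i_wax_sample - i_air_sample) / i_wax_sample
    k = cf_p / cf_s
    return sample_data.astype(np.float64) * k - k * i_air_sample
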