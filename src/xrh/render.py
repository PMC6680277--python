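"""Volume visualization primitives: MIP, rotating MIP, MPR and oblique reslicing.

Orientation convention for all extracted 2D images: ``image[row, col]`` with
the plane's ``u`` axis along columns (left to right) and ``v`` axis along
rows (top to bottom). Samples falling outside the volume are padded with 0,
the calibrated gray value of air.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume_io import Volume

__all__ = [
    "PlaneSpec",
    "RenderSettings",
    "apply_window",
    "mip",
    "rotating_mip",
    "orthogonal_views",
    "oblique_slice",
]

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}
# projection direction used for frame 0 when rotating about a given axis
_ROTATION_PROJECTION = {"z": "y", "y": "x", "x": "z"}


@dataclass(frozen=True)
class PlaneSpec:
    """Oriented sampling plane in voxel coordinates (z, y, x).

    ``image[i, j]`` samples the volume at
    ``origin + i * sample_spacing * v_axis + j * sample_spacing * u_axis``.
    """

    origin: tuple[float, float, float]
    u_axis: tuple[float, float, float]
    v_axis: tuple[float, float, float]
    extent: tuple[int, int]  # (width_px, height_px)
    sample_spacing: float = 1.0

    def __post_init__(self) -> None:
        u = np.asarray(self.u_axis, dtype=np.float64)
        v = np.asarray(self.v_axis, dtype=np.float64)
        if not (
            abs(np.linalg.norm(u) - 1.0) < 1e-6
            and abs(np.linalg.norm(v) - 1.0) < 1e-6
            and abs(float(u @ v)) < 1e-6
        ):
            raise ValueError("u_axis and v_axis must be orthonormal unit vectors")
        if self.extent[0] < 1 or self.extent[1] < 1:
            raise ValueError("plane extent must be positive")
        if not self.sample_spacing > 0:
            raise ValueError("sample_spacing must be > 0")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)


@dataclass(frozen=True)
class RenderSettings:
    """Display window: gray values in level ± width/2 map linearly to [0, 1]."""

    window_level: float
    window_width: float

    def __post_init__(self) -> None:
        if not self.window_width > 0:
            raise ValueError("window_width must be > 0")


def apply_window(image: np.ndarray, settings: RenderSettings) -> np.ndarray:
    lo = settings.window_level - settings.window_width / 2.0
    out = (image.astype(np.float64) - lo) / settings.window_width
    return np.clip(out, 0.0, 1.0)


def _unit(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix (zyx convention) mapping ``direction`` onto the +z axis."""
    d = _unit(direction)
    z = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x) component order
    v = np.cross(d, z)
    c = float(d @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, 1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _resample_rotated(volume: Volume, rot: np.ndarray) -> np.ndarray:
    """Trilinear resampling of the volume onto a grid rotated about its centre."""
    center = (np.asarray(volume.data.shape, dtype=np.float64) - 1.0) / 2.0
    # affine_transform maps output coords -> input coords: x_in = M x_out + off
    matrix = rot.T
    offset = center - matrix @ center
    return ndi.affine_transform(
        volume.data.astype(np.float64),
        matrix,
        offset=offset,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def mip(
    volume: Volume,
    direction: str | tuple[float, float, float] = "z",
    settings: RenderSettings | None = None,
) -> np.ndarray:
    """Maximum intensity projection: the brightest voxel along each ray path.

    Axis-aligned directions ('z', 'y', 'x') take exact per-column maxima.
    An arbitrary unit vector (z, y, x components) first resamples the volume
    onto a rotated grid (trilinear) so the requested direction becomes the
    projection axis, then takes per-column maxima.
    """
    if isinstance(direction, str):
        if direction not in _AXIS_INDEX:
            raise ValueError(f"unknown axis {direction!r}")
        image = volume.data.max(axis=_AXIS_INDEX[direction])
    else:
        rot = _rotation_to_z(np.asarray(direction, dtype=np.float64))
        image = _resample_rotated(volume, rot).max(axis=0)
    if settings is not None:
        image = apply_window(image, settings)
    return image


def rotating_mip(
    volume: Volume,
    axis: str = "z",
    n_angles: int = 8,
    settings: RenderSettings | None = None,
) -> list[np.ndarray]:
    """Sequence of MIPs while rotating the volume about one axis over 360°.

    Frame k rotates the volume by ``k * 360 / n_angles`` degrees about
    ``axis`` and projects along a fixed perpendicular axis; frame 0 is the
    plain :func:`mip` along that axis. Played as a loop, the sequence gives
    the depth cue a single MIP lacks.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"unknown axis {axis!r}")
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")
    proj_axis = _ROTATION_PROJECTION[axis]
    frames = []
    ax_vec = np.zeros(3)
    ax_vec[_AXIS_INDEX[axis]] = 1.0
    for k in range(n_angles):
        theta = 2.0 * np.pi * k / n_angles
        if k == 0:
            rotated = volume.data.astype(np.float64)
        else:
            rot = _axis_angle_matrix(ax_vec, theta)
            rotated = _resample_rotated(volume, rot)
        image = rotated.max(axis=_AXIS_INDEX[proj_axis])
        if settings is not None:
            image = apply_window(image, settings)
        frames.append(image)
    return frames


def _axis_angle_matrix(axis_vec: np.ndarray, theta: float) -> np.ndarray:
    a = _unit(axis_vec)
    c, s = np.cos(theta), np.sin(theta)
    ax = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * ax + (1 - c) * np.outer(a, a)


def orthogonal_views(
    volume: Volume, point: tuple[int, int, int]
) -> dict[str, np.ndarray]:
    """The three principal MPR views through a voxel: XY, YZ and XZ slices.

    XY is ``data[z]`` (rows y, cols x); YZ is ``data[:, :, x]`` (rows z,
    cols y); XZ is ``data[:, y, :]`` (rows z, cols x). No interpolation.
    """
    z, y, x = (int(c) for c in point)
    nz, ny, nx = volume.data.shape
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise ValueError(f"point {point} outside volume of shape {(nz, ny, nx)}")
    return {
        "xy": volume.data[z],
        "yz": volume.data[:, :, x],
        "xz": volume.data[:, y, :],
    }


def oblique_slice(
    volume: Volume, plane: PlaneSpec, interpolation: str = "bicubic"
) -> np.ndarray:
    """Resample the volume on an arbitrary oriented plane.

    ``bicubic`` uses interpolating cubic-spline resampling, ``trilinear``
    linear resampling. When every sample coordinate falls exactly on the
    voxel lattice the values are gathered directly, so lattice-aligned
    planes reproduce stored slices bit-exactly. Out-of-volume samples are 0.
    """
    if interpolation not in ("bicubic", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    w, h = plane.extent
    origin = np.asarray(plane.origin, dtype=np.float64)
    u = np.asarray(plane.u_axis, dtype=np.float64)
    v = np.asarray(plane.v_axis, dtype=np.float64)
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = (
        origin[:, None, None]
        + ii[None] * plane.sample_spacing * v[:, None, None]
        + jj[None] * plane.sample_spacing * u[:, None, None]
    )

    rounded = np.round(coords)
    if np.allclose(coords, rounded, atol=1e-9):
        idx = rounded.astype(np.int64)
        inside = np.ones(idx.shape[1:], dtype=bool)
        for d in range(3):
            inside &= (idx[d] >= 0) & (idx[d] < volume.data.shape[d])
        idx_clipped = [np.clip(idx[d], 0, volume.data.shape[d] - 1) for d in range(3)]
        image = volume.data[tuple(idx_clipped)]
        return np.where(inside, image, np.zeros((), dtype=volume.data.dtype))

    order = 3 if interpolation == "bicubic" else 1
    return ndi.map_coordinates(
        volume.data.astype(np.float64),
        coords,
        order=order,
        mode="constant",
        cval=0.0,
    )
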