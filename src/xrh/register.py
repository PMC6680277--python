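"""Coregistration of 2D histology slides with the 3D μCT volume.

The workflow mirrors the manual protocol used at the microscope: at least
three landmark features visible in the histology slide are located in the
μCT volume; a plane is fitted to the 3D landmarks (total least squares); the
volume is resampled on that plane (bicubic) to produce the matching virtual
section, with a stack of candidate slices at offsets along the plane normal
for visual selection; finally the histology image is warped elastically onto
the chosen CT slice with a landmark-interpolating thin-plate spline, which
compensates the distortions introduced by mechanical sectioning.

Landmark files are plain CSV with header ``x2d,y2d,x3d,y3d,z3d`` (zero-based
pixel / voxel coordinates). All 2D points are (x, y) = (column, row); 3D
points are converted internally to the package's (z, y, x) voxel order.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .render import PlaneSpec, oblique_slice
from .volume_io import Volume

__all__ = [
    "LandmarkSet",
    "Warp2D",
    "read_landmarks",
    "fit_plane",
    "match_slice",
    "elastic_register",
    "registration_report",
    "normalized_cross_correlation",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Paired 2D histology-pixel and 3D volume-voxel landmark coordinates.

    ``p2d`` has shape (n, 2) as (x, y); ``p3d`` has shape (n, 3) as (z, y, x).
    """

    p2d: np.ndarray
    p3d: np.ndarray

    def __post_init__(self) -> None:
        p2d = np.asarray(self.p2d, dtype=np.float64)
        p3d = np.asarray(self.p3d, dtype=np.float64)
        if p2d.ndim != 2 or p2d.shape[1] != 2 or p3d.shape != (p2d.shape[0], 3):
            raise ValueError("landmarks must be (n,2) 2D and (n,3) 3D point arrays")
        if p2d.shape[0] < 3:
            raise ValueError("at least three landmark pairs are required")
        object.__setattr__(self, "p2d", p2d)
        object.__setattr__(self, "p3d", p3d)

    def __len__(self) -> int:
        return self.p2d.shape[0]


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV (header ``x2d,y2d,x3d,y3d,z3d``)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"x2d", "y2d", "x3d", "y3d", "z3d"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"landmark file must have columns {sorted(required)}")
        p2d, p3d = [], []
        for row in reader:
            p2d.append((float(row["x2d"]), float(row["y2d"])))
            p3d.append((float(row["z3d"]), float(row["y3d"]), float(row["x3d"])))
    return LandmarkSet(np.array(p2d), np.array(p3d))


def fit_plane(
    landmarks: LandmarkSet,
    extent: tuple[int, int] | None = None,
    margin_px: float = 10.0,
) -> PlaneSpec:
    """Total-least-squares plane through the 3D landmarks.

    The normal is the smallest principal direction of the centred points
    (SVD). The in-plane basis is fixed deterministically: ``u`` is the
    projection onto the plane of the lattice axis most parallel to it
    (preference order x, y, z — so cassette-parallel planes get u = x,
    v = y, matching the stored-slice orientation), and ``v = u × n``. For
    exactly axis-aligned planes the origin snaps to the voxel lattice, so
    the resampled image reproduces stored gray values bit-exactly.
    """
    pts = landmarks.p3d
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=True)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("landmarks are collinear; plane is undefined")
    n = vt[2]
    # lattice axes in (z, y, x) component order, preference x, y, z
    axes = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])]
    e = min(axes, key=lambda a: abs(float(a @ n)))
    u = e - (e @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(u, n)
    v /= np.linalg.norm(v)

    proj_u = centered @ u
    proj_v = centered @ v
    if extent is None:
        w = int(np.ceil(proj_u.max() - proj_u.min() + 2 * margin_px)) + 1
        h = int(np.ceil(proj_v.max() - proj_v.min() + 2 * margin_px)) + 1
        origin = centroid + (proj_u.min() - margin_px) * u + (proj_v.min() - margin_px) * v
    else:
        w, h = extent
        origin = centroid - (w - 1) / 2.0 * u - (h - 1) / 2.0 * v
    if np.max(np.abs(n)) > 1.0 - 1e-9:
        origin = np.round(origin)  # axis-aligned: sample on the lattice
    return PlaneSpec(
        origin=tuple(origin),
        u_axis=tuple(u),
        v_axis=tuple(v),
        extent=(w, h),
    )


def match_slice(
    volume: Volume,
    landmarks: LandmarkSet,
    offset_range: float = 3.0,
    offset_step: float = 1.0,
    interpolation: str = "bicubic",
    histology: np.ndarray | None = None,
):
    """Extract the virtual section matching the landmarks, plus candidates.

    Returns ``(image, plane, candidates)`` where ``candidates`` is a list of
    ``(offset_voxels, image, score)`` at offsets along the fitted plane's
    normal in ``[-offset_range, +offset_range]`` steps of ``offset_step``.
    The score is the normalized cross-correlation against ``histology``
    (converted to luminance) when given, else ``None`` — ranking assists the
    choice of the best-matching slice, it never replaces visual selection.
    """
    plane = fit_plane(landmarks)
    shape = np.asarray(volume.data.shape, dtype=np.float64)
    centroid = landmarks.p3d.mean(axis=0)
    if np.any(centroid < -0.5) or np.any(centroid > shape - 0.5):
        raise ValueError("fitted plane lies outside the volume")
    normal = plane.normal
    offsets = np.arange(-offset_range, offset_range + 1e-9, offset_step)
    hist_gray = to_grayscale(histology) if histology is not None else None
    candidates = []
    for off in offsets:
        p = PlaneSpec(
            origin=tuple(np.asarray(plane.origin) + off * normal),
            u_axis=plane.u_axis,
            v_axis=plane.v_axis,
            extent=plane.extent,
            sample_spacing=plane.sample_spacing,
        )
        img = oblique_slice(volume, p, interpolation=interpolation)
        score = None
        if hist_gray is not None:
            resized = _resample_to(hist_gray, img.shape)
            score = normalized_cross_correlation(img.astype(np.float64), resized)
        candidates.append((float(off), img, score))
    image = next(img for off, img, _ in candidates if abs(off) < 1e-12)
    return image, plane, candidates


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance of an RGB(A) image; grayscale images pass through."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    return image[..., 0] * 0.2126 + image[..., 1] * 0.7152 + image[..., 2] * 0.0722


def _resample_to(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zoom = (shape[0] / image.shape[0], shape[1] / image.shape[1])
    return ndi.zoom(image, zoom, order=1)


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


# ---------------------------------------------------------------------------
# thin-plate-spline elastic warp
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 * r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


def _tps_fit(src: np.ndarray, dst: np.ndarray, reg: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve the TPS system; returns (radial (n,2), affine (3,2)) coefficients."""
    n = src.shape[0]
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2) + reg * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    coeffs = np.linalg.solve(L, rhs)
    return coeffs[:n], coeffs[n:]


def _tps_eval(
    pts: np.ndarray, src: np.ndarray, radial: np.ndarray, affine: np.ndarray
) -> np.ndarray:
    d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    U = _tps_kernel(d2)
    return affine[0] + pts @ affine[1:] + U @ radial


@dataclass(frozen=True)
class Warp2D:
    """Landmark-interpolating 2D thin-plate-spline warp.

    The forward map sends moving-image (source) coordinates to target
    coordinates and interpolates the landmarks exactly when
    ``regularization == 0``; the stored inverse-direction spline (target →
    source) is what image resampling uses. Coefficients are split into an
    affine part (3, 2) and radial-basis weights (n, 2) per output dimension;
    for point sets related by a pure affine map the radial weights vanish.
    """

    src: np.ndarray
    dst: np.ndarray
    affine: np.ndarray
    radial: np.ndarray
    inv_affine: np.ndarray
    inv_radial: np.ndarray
    regularization: float
    domain: tuple[int, int]  # (height, width) of the target image
    affine_only: bool = False

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Forward transform of (n, 2) points in (x, y) order."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        if self.affine_only:
            return self.affine[0] + pts @ self.affine[1:]
        return _tps_eval(pts, self.src, self.radial, self.affine)

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        """Target → source transform of (n, 2) points in (x, y) order."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        if self.affine_only:
            return self.inv_affine[0] + pts @ self.inv_affine[1:]
        return _tps_eval(pts, self.dst, self.inv_radial, self.inv_affine)


def _affine_lstsq(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    P = np.hstack([np.ones((src.shape[0], 1)), src])
    coef, *_ = np.linalg.lstsq(P, dst, rcond=None)
    return coef


def elastic_register(
    moving: np.ndarray,
    target: np.ndarray,
    src2d: np.ndarray,
    dst2d: np.ndarray,
    regularization: float = 0.0,
) -> tuple[Warp2D, np.ndarray]:
    """Elastically warp ``moving`` (histology) onto ``target`` (CT slice).

    ``src2d``/``dst2d`` are (n >= 3, 2) landmark arrays in (x, y) pixel
    coordinates of the moving and target images. With
    ``regularization == 0`` the thin-plate spline interpolates: every source
    landmark maps exactly onto its target. Larger values trade landmark
    fidelity for smoothness. Collinear landmarks degrade the spline system;
    in that case an affine-only least-squares warp is fitted with a warning.

    Returns the :class:`Warp2D` and the moving image resampled (bicubic)
    onto the target frame; color images are warped per channel.
    """
    src = np.asarray(src2d, dtype=np.float64)
    dst = np.asarray(dst2d, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2 or src.shape[0] < 3:
        raise ValueError("need matching (n>=3, 2) landmark arrays")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")

    centered = src - src.mean(axis=0)
    degenerate = np.linalg.svd(centered, compute_uv=False)[1] < 1e-9
    if degenerate:
        warnings.warn(
            "collinear landmarks: falling back to an affine-only warp", stacklevel=2
        )
        affine = _affine_lstsq(src, dst)
        inv_affine = _affine_lstsq(dst, src)
        warp = Warp2D(
            src=src,
            dst=dst,
            affine=affine,
            radial=np.zeros((src.shape[0], 2)),
            inv_affine=inv_affine,
            inv_radial=np.zeros((src.shape[0], 2)),
            regularization=regularization,
            domain=target.shape[:2],
            affine_only=True,
        )
    else:
        radial, affine = _tps_fit(src, dst, regularization)
        inv_radial, inv_affine = _tps_fit(dst, src, regularization)
        warp = Warp2D(
            src=src,
            dst=dst,
            affine=affine,
            radial=radial,
            inv_affine=inv_affine,
            inv_radial=inv_radial,
            regularization=regularization,
            domain=target.shape[:2],
        )

    h, w = target.shape[:2]
    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    sample = warp.inverse(pts)  # moving-image (x, y) for each target pixel
    coords = np.stack([sample[:, 1].reshape(h, w), sample[:, 0].reshape(h, w)])

    moving = np.asarray(moving)
    if moving.ndim == 2:
        warped = ndi.map_coordinates(
            moving.astype(np.float64), coords, order=3, mode="constant", cval=0.0
        )
    else:
        warped = np.stack(
            [
                ndi.map_coordinates(
                    moving[..., c].astype(np.float64),
                    coords,
                    order=3,
                    mode="constant",
                    cval=0.0,
                )
                for c in range(moving.shape[-1])
            ],
            axis=-1,
        )
    return warp, warped


def registration_report(warp: Warp2D, grid_step: int = 4) -> dict:
    """Residuals at landmarks plus a deformation-magnitude map over the domain.

    The deformation magnitude ``|f(x) - x|`` quantifies how far the histology
    image had to be unwrapped to reach its undistorted state.
    """
    mapped = warp(warp.src)
    residuals = np.linalg.norm(mapped - warp.dst, axis=1)
    h, w = warp.domain
    xs = np.arange(0, w, grid_step)
    ys = np.arange(0, h, grid_step)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    disp = warp(pts) - pts
    mag = np.linalg.norm(disp, axis=1).reshape(len(ys), len(xs))
    return {
        "landmark_residuals_px": residuals,
        "mean_residual_px": float(residuals.mean()),
        "max_residual_px": float(residuals.max()),
        "mean_displacement_px": float(mag.mean()),
        "max_displacement_px": float(mag.max()),
        "displacement_magnitude_map": mag,
    }
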