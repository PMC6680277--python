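"""Volume input/output and coordinate conventions.

Every module in the package shares one convention: a volume is a 3D scalar
grid indexed ``data[z, y, x]`` (zero-based), the XY plane (fixed ``z``) is the
plane parallel to the histology cassette, and the physical coordinate of a
voxel centre is ``index * voxel_size_um``.

Two on-disk formats are supported:

* multi-page grayscale TIFF stacks (page order = z), 16-bit unsigned or
  32-bit float, via :mod:`tifffile`;
* headerless raw binary (little-endian, C order) accompanied by a small JSON
  sidecar describing shape, dtype, voxel size and calibration state.
  Reconstructed volumes from lab scanners are typically written exactly like
  this, with no embedded header, so the sidecar is mandatory — no guessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VolumeMeta",
    "Volume",
    "new_volume",
    "read_volume",
    "write_volume",
    "read_sidecar",
    "write_image",
    "read_image",
]

_DTYPE_TAGS = {"float32": np.float32, "uint16": np.uint16, "uint8": np.uint8}
_CALIBRATION_STATES = ("raw", "preprocessed", "calibrated")


@dataclass(frozen=True)
class VolumeMeta:
    """Voxel metadata: isotropic voxel size (μm), grid shape and pipeline state."""

    voxel_size_um: float
    shape: tuple[int, int, int]  # (nz, ny, nx)
    dtype_tag: str = "float32"
    calibration_state: str = "raw"

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive (nz, ny, nx) triple, got {self.shape}")
        if self.dtype_tag not in _DTYPE_TAGS:
            raise ValueError(f"unsupported dtype_tag {self.dtype_tag!r}")
        if self.calibration_state not in _CALIBRATION_STATES:
            raise ValueError(f"unknown calibration_state {self.calibration_state!r}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(_DTYPE_TAGS[self.dtype_tag])


@dataclass(frozen=True)
class Volume:
    """A 3D scalar grid ``data[z, y, x]`` plus its :class:`VolumeMeta`."""

    meta: VolumeMeta
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.meta.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match meta.shape {self.meta.shape}"
            )
        if self.data.dtype != self.meta.dtype:
            raise ValueError(
                f"data dtype {self.data.dtype} does not match meta dtype_tag "
                f"{self.meta.dtype_tag!r}"
            )

    @property
    def voxel_size_um(self) -> float:
        return self.meta.voxel_size_um

    def with_data(self, data: np.ndarray, calibration_state: str | None = None) -> "Volume":
        """Same geometry, new voxel values (and optionally a new pipeline state)."""
        tag = {v: k for k, v in _DTYPE_TAGS.items()}[data.dtype.type]
        meta = replace(
            self.meta,
            shape=tuple(data.shape),
            dtype_tag=tag,
            calibration_state=calibration_state or self.meta.calibration_state,
        )
        return Volume(meta, data)


def new_volume(
    data: np.ndarray,
    voxel_size_um: float,
    calibration_state: str = "raw",
) -> Volume:
    """Wrap an array (cast to a supported dtype if needed) into a :class:`Volume`."""
    data = np.asarray(data)
    if data.dtype.type not in {v for v in _DTYPE_TAGS.values()}:
        data = data.astype(np.float32)
    tag = {v: k for k, v in _DTYPE_TAGS.items()}[data.dtype.type]
    meta = VolumeMeta(voxel_size_um, tuple(data.shape), tag, calibration_state)
    return Volume(meta, data)


# ---------------------------------------------------------------------------
# raw + sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(raw_path: Path) -> Path:
    return raw_path.with_suffix(raw_path.suffix + ".json")


def write_sidecar(meta: VolumeMeta, path: Path) -> None:
    payload = {
        "shape": list(meta.shape),
        "dtype": meta.dtype_tag,
        "voxel_size_um": meta.voxel_size_um,
        "endianness": "little",
        "calibration_state": meta.calibration_state,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sidecar(path: Path) -> VolumeMeta:
    payload = json.loads(Path(path).read_text())
    if payload.get("endianness", "little") != "little":
        raise ValueError("only little-endian raw volumes are supported")
    return VolumeMeta(
        voxel_size_um=float(payload["voxel_size_um"]),
        shape=tuple(payload["shape"]),
        dtype_tag=payload["dtype"],
        calibration_state=payload.get("calibration_state", "raw"),
    )


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, meta: VolumeMeta | str | Path | None = None) -> Volume:
    """Read a volume from a TIFF stack or a raw file.

    ``meta`` is a :class:`VolumeMeta`, a path to a JSON sidecar, or ``None``.
    Raw files require metadata (argument or the default ``<file>.json``
    sidecar); for TIFF stacks the shape/dtype come from the file and only
    voxel size / calibration state are taken from the metadata (voxel size
    defaults to 1 μm if no metadata is given).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(meta, (str, Path)):
        meta = read_sidecar(meta)

    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise ValueError(f"expected a grayscale TIFF stack, got ndim={data.ndim}")
        if data.dtype.type not in _DTYPE_TAGS.values():
            raise ValueError(f"unsupported TIFF dtype {data.dtype}")
        if meta is None and _sidecar_path(path).exists():
            meta = read_sidecar(_sidecar_path(path))
        if meta is None:
            return new_volume(data, voxel_size_um=1.0)
        if meta.shape != tuple(data.shape):
            raise ValueError(
                f"declared shape {meta.shape} does not match TIFF stack shape {data.shape}"
            )
        return new_volume(data, meta.voxel_size_um, meta.calibration_state)

    if meta is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"raw volume {path} needs metadata (sidecar {sidecar} not found)")
        meta = read_sidecar(sidecar)
    expected = int(np.prod(meta.shape)) * meta.dtype.itemsize
    actual = path.stat().st_size
    if expected != actual:
        raise ValueError(
            f"raw file size {actual} B does not match declared shape {meta.shape} "
            f"and dtype {meta.dtype_tag} ({expected} B)"
        )
    data = np.fromfile(path, dtype=meta.dtype.newbyteorder("<")).astype(meta.dtype)
    return Volume(meta, data.reshape(meta.shape))


def write_volume(volume: Volume, path: str | Path, format: str | None = None) -> None:
    """Write a volume as ``raw+sidecar`` or ``tiff_stack`` (inferred from suffix).

    TIFF stacks are written one page per z-slice. Float volumes are refused
    for ``tiff_stack``: window/quantize to 16 bit first (an explicit, not
    silent, conversion).
    """
    path = Path(path)
    if format is None:
        format = "tiff_stack" if path.suffix.lower() in (".tif", ".tiff") else "raw+sidecar"
    if format == "tiff_stack":
        if volume.data.dtype.kind == "f":
            raise ValueError(
                "refusing to write a float volume as a 16-bit TIFF stack: "
                "apply window_and_quantize first"
            )
        tifffile.imwrite(path, volume.data, photometric="minisblack")
        write_sidecar(volume.meta, _sidecar_path(path))
    elif format == "raw+sidecar":
        volume.data.astype(volume.data.dtype.newbyteorder("<")).tofile(path)
        write_sidecar(volume.meta, _sidecar_path(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# 2D image export (PNG / single-page TIFF)
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a 2D image (grayscale or RGB). Floats in [0, 1] are scaled to 8 bit."""
    import imageio.v3 as iio

    image = np.asarray(image)
    if image.dtype.kind == "f":
        image = np.clip(image, 0.0, 1.0)
        image = np.round(image * 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)
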