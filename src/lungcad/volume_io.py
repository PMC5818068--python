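"""CT volume container, MetaImage I/O, slice-thickness downsampling.

Volumes are held as (x, y, z)-ordered arrays of Hounsfield units with an
affine per-axis geometry ``world = origin + index * spacing`` (0-based
indices, world coordinates in mm).  Slice thickness is operationalized as
z-spacing: every supported acquisition has thickness equal to spacing, and
inputs where the two differ are rejected at the harness level.

Thicker slices are simulated by slab averaging: groups of ``ratio``
consecutive slices are replaced by their arithmetic mean, preserving
Hounsfield units (the post-reconstruction average density of a slab equals
the mean of its constituent thin slices under ideal reconstruction).
Annotations are never edited during resampling; only the geometry changes,
so world-mm cue points remain authoritative across thicknesses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

HU_MIN = -1024
HU_MAX = 3071

__all__ = [
    "CTVolume",
    "VolumeGeometry",
    "MetaImageError",
    "MissingRawFileError",
    "ShapeMismatchError",
    "UnsupportedElementTypeError",
    "read_metaimage",
    "write_metaimage",
    "downsample_slices",
    "world_to_voxel",
    "voxel_to_world",
    "nearest_voxel",
]


class MetaImageError(ValueError):
    """Malformed or inconsistent MetaImage header/raw pair."""


class MissingRawFileError(MetaImageError):
    """Header points at a raw file that does not exist."""


class ShapeMismatchError(MetaImageError):
    """Raw file size disagrees with the header's DimSize/ElementType."""


class UnsupportedElementTypeError(MetaImageError):
    """ElementType outside the supported scalar set."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid geometry without voxel data: shape, spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("geometry must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")


@dataclass
class CTVolume:
    """A CT volume: HU voxels indexed ``data[x, y, z]`` plus geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be 3-D (x, y, z)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.shape, self.spacing, self.origin)


def world_to_voxel(geom: VolumeGeometry, world_mm) -> np.ndarray:
    """Continuous voxel index of a world-mm point: (world - origin) / spacing."""
    world = np.asarray(world_mm, dtype=float)
    return (world - np.asarray(geom.origin)) / np.asarray(geom.spacing)


def voxel_to_world(geom: VolumeGeometry, index) -> np.ndarray:
    """Inverse of :func:`world_to_voxel`; exact for any continuous index."""
    idx = np.asarray(index, dtype=float)
    return np.asarray(geom.origin) + idx * np.asarray(geom.spacing)


def nearest_voxel(geom: VolumeGeometry, world_mm) -> tuple[int, int, int]:
    """Round a world point to its voxel; error if > 0.5 voxel outside the grid."""
    cont = world_to_voxel(geom, world_mm)
    shape = np.asarray(geom.shape)
    if np.any(cont < -0.5) or np.any(cont > shape - 0.5):
        raise ValueError(
            f"world point {tuple(np.asarray(world_mm, float))} maps to index "
            f"{tuple(cont)} outside grid {geom.shape}"
        )
    idx = np.clip(np.rint(cont).astype(int), 0, shape - 1)
    return tuple(int(i) for i in idx)


# MetaImage element types we accept, with byte widths for the size check.
_ELEMENT_BYTES = {
    "MET_CHAR": 1,
    "MET_UCHAR": 1,
    "MET_SHORT": 2,
    "MET_USHORT": 2,
    "MET_INT": 4,
    "MET_UINT": 4,
    "MET_FLOAT": 4,
    "MET_DOUBLE": 8,
}

_DTYPE_TO_MET = {
    np.dtype(np.int16): "MET_SHORT",
    np.dtype(np.uint8): "MET_UCHAR",
    np.dtype(np.int8): "MET_CHAR",
    np.dtype(np.uint16): "MET_USHORT",
    np.dtype(np.int32): "MET_INT",
    np.dtype(np.float32): "MET_FLOAT",
    np.dtype(np.float64): "MET_DOUBLE",
}


def _parse_mhd_header(path: Path) -> dict[str, str]:
    header: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        header[key.strip()] = value.strip()
    return header


def _validate_mhd(path: Path) -> None:
    """Pre-validate header/raw consistency to surface distinct parse errors."""
    header = _parse_mhd_header(path)
    etype = header.get("ElementType", "")
    if etype not in _ELEMENT_BYTES:
        raise UnsupportedElementTypeError(f"{path}: unsupported ElementType {etype!r}")
    datafile = header.get("ElementDataFile", "")
    if datafile in ("", "LOCAL"):
        return  # raw embedded; let the reader handle it
    raw = path.parent / datafile
    if not raw.exists():
        raise MissingRawFileError(f"{path}: raw file {raw} not found")
    if header.get("CompressedData", "False").lower() == "true":
        return  # compressed byte count is not predictable from DimSize
    try:
        dims = [int(v) for v in header.get("DimSize", "").split()]
    except ValueError as exc:
        raise MetaImageError(f"{path}: unparsable DimSize") from exc
    channels = int(header.get("ElementNumberOfChannels", "1"))
    expected = int(np.prod(dims)) * _ELEMENT_BYTES[etype] * channels
    actual = raw.stat().st_size
    if expected != actual:
        raise ShapeMismatchError(
            f"{path}: raw file holds {actual} bytes, header promises {expected}"
        )


def read_metaimage(path) -> CTVolume:
    """Read an .mhd/.raw pair into a CTVolume (x, y, z order)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_mhd(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return CTVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_metaimage(vol: CTVolume, path, dtype=np.int16) -> None:
    """Write an uncompressed .mhd/.raw pair; HU volumes are stored as int16.

    Integer targets are clipped to the representable HU range before the
    cast so overflow can never wrap.
    """
    path = Path(path)
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_TO_MET:
        raise UnsupportedElementTypeError(f"cannot store dtype {dtype}")
    data = vol.data
    if np.issubdtype(dtype, np.integer) and not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data)
    if dtype == np.dtype(np.int16):
        data = np.clip(data, HU_MIN, HU_MAX)
    data = data.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path), useCompression=False)


def downsample_slices(vol: CTVolume, ratio: int) -> CTVolume:
    """Simulate a thicker acquisition by averaging groups of ``ratio`` slices.

    Output slice ``k`` is the arithmetic mean (double precision) of input
    slices ``[k*ratio, (k+1)*ratio)``; z-spacing is multiplied by ``ratio``
    and the z-origin shifted by ``(ratio-1)/2`` input spacings so each slab
    carries the world position of its center.  Trailing slices that do not
    fill a complete group are dropped with a warning, so every output slab
    represents the same physical thickness.  Integer inputs are re-stored in
    their own dtype with round-half-to-even; float inputs stay float.
    """
    if not float(ratio).is_integer() or int(ratio) < 2:
        raise ValueError(f"downsampling ratio must be an integer >= 2, got {ratio}")
    ratio = int(ratio)
    if ratio not in (2, 4, 8):
        warnings.warn(f"non-standard downsampling ratio {ratio}", stacklevel=2)
    nx, ny, nz = vol.data.shape
    if nz < ratio:
        raise ValueError(f"volume has {nz} slices, fewer than ratio {ratio}")
    n_out = nz // ratio
    if nz % ratio:
        warnings.warn(
            f"dropping {nz % ratio} trailing slice(s) not filling a full slab",
            stacklevel=2,
        )
    trimmed = vol.data[:, :, : n_out * ratio].astype(np.float64)
    averaged = trimmed.reshape(nx, ny, n_out, ratio).mean(axis=3)
    if np.issubdtype(vol.data.dtype, np.integer):
        out = np.rint(averaged).astype(vol.data.dtype)  # round half to even
    else:
        out = averaged.astype(vol.data.dtype)
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    return CTVolume(
        out,
        (sx, sy, sz * ratio),
        (ox, oy, oz + (ratio - 1) / 2.0 * sz),
    )
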