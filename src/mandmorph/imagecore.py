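"""Volume container, I/O and preprocessing.

Axis convention: arrays are indexed ``data[i, j, k]`` with

* axis 0 (x): left-right (left = negative x in physical mm),
* axis 1 (y): rostral-caudal (rostral = +y),
* axis 2 (z): ventral-dorsal (dorsal = +z).

Voxel indices are zero-based; the physical coordinate of voxel ``(i, j, k)``
is its *center*: ``origin + spacing * (i, j, k)``.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """3D scalar grid with physical spacing and origin (both mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("Volume data must be a non-empty 3D array")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        self.spacing = tuple(float(s) for s in sp)
        self.origin = tuple(float(o) for o in np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(
            self.origin
        )

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 3) mm coordinates to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates of every voxel along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)

    def is_mask(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())


@dataclass(frozen=True)
class BoundingBox:
    """Per-axis [lo, hi) voxel index ranges, zero-based half-open."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        if any(l >= h for l, h in zip(lo, hi)):
            raise ValueError(f"empty bounding box {lo}..{hi}")
        if any(l < 0 for l in lo):
            raise ValueError(f"bounding box lower corner {lo} is negative")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @classmethod
    def from_mm(cls, volume: Volume, lo_mm, hi_mm) -> "BoundingBox":
        """Smallest voxel box whose voxel centers cover [lo_mm, hi_mm]."""
        lo = np.floor(volume.physical_to_index(lo_mm)).astype(int)
        hi = np.ceil(volume.physical_to_index(hi_mm)).astype(int) + 1
        lo = np.clip(lo, 0, np.asarray(volume.shape) - 1)
        hi = np.clip(hi, 1, volume.shape)
        return cls(tuple(lo), tuple(hi))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("nifti", "metaimage", "tiff_stack")


def _guess_format(path: str | Path) -> str:
    s = str(path)
    if s.endswith((".nii", ".nii.gz")):
        return "nifti"
    if s.endswith((".mha", ".mhd")):
        return "metaimage"
    if os.path.isdir(s) or s.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from {path!r}")


def read_volume(path, format: str | None = None, spacing=None, origin=None) -> Volume:
    """Read a volume with physical spacing from NIfTI, MetaImage or TIFF stack.

    ``spacing``/``origin`` override header metadata; for TIFF stacks (which
    carry no physical spacing) ``spacing`` is required.
    """
    fmt = format or _guess_format(path)
    if fmt == "nifti":
        vol = _read_nifti(path)
    elif fmt == "metaimage":
        vol = _read_metaimage(path)
    elif fmt == "tiff_stack":
        if spacing is None:
            raise ValueError(
                "tiff_stack carries no physical spacing: pass spacing=(sx, sy, sz) mm"
            )
        vol = _read_tiff_stack(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if spacing is not None:
        vol.spacing = tuple(float(s) for s in spacing)
    if origin is not None:
        vol.origin = tuple(float(o) for o in origin)
    return vol


def write_volume(volume: Volume, path, format: str | None = None) -> None:
    fmt = format or _guess_format(path)
    if fmt == "nifti":
        _write_nifti(volume, path)
    elif fmt == "metaimage":
        _write_metaimage(volume, path)
    elif fmt == "tiff_stack":
        _write_tiff_stack(volume, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def _read_nifti(path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return Volume(data, spacing, origin)


def _write_nifti(volume: Volume, path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    nib.save(img, str(path))


_MHA_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MHA_TYPES_INV = {np.dtype(v): k for k, v in _MHA_TYPES.items()}


def _read_metaimage(path) -> Volume:
    # Minimal MetaImage (.mha, local uncompressed raw) reader.
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode("ascii")
            if not line:
                raise ValueError(f"{path}: truncated MetaImage header")
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                if value.strip() != "LOCAL":
                    raise ValueError("only ElementDataFile = LOCAL is supported")
                raw = fh.read()
                break
    if header.get("CompressedData", "False").lower() == "true":
        raise ValueError("compressed MetaImage is not supported")
    dims = tuple(int(v) for v in header["DimSize"].split())
    dtype = _MHA_TYPES[header["ElementType"]]
    spacing = tuple(float(v) for v in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in header.get("Offset", "0 0 0").split())
    data = np.frombuffer(raw, dtype=dtype, count=int(np.prod(dims)))
    # MetaImage raw order is x-fastest; our arrays index (x, y, z)
    data = data.reshape(dims[::-1]).transpose(2, 1, 0)
    return Volume(data.copy(), spacing, origin)


def _write_metaimage(volume: Volume, path) -> None:
    data = np.asarray(volume.data)
    dtype = np.dtype(data.dtype)
    if dtype == np.dtype(bool):
        data, dtype = data.astype(np.uint8), np.dtype(np.uint8)
    if dtype not in _MHA_TYPES_INV:
        data, dtype = data.astype(np.float32), np.dtype(np.float32)
    hdr = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {volume.shape[0]} {volume.shape[1]} {volume.shape[2]}\n"
        f"ElementSpacing = {volume.spacing[0]} {volume.spacing[1]} {volume.spacing[2]}\n"
        f"Offset = {volume.origin[0]} {volume.origin[1]} {volume.origin[2]}\n"
        f"ElementType = {_MHA_TYPES_INV[dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(hdr.encode("ascii"))
        fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def _read_tiff_stack(path) -> Volume:
    import tifffile

    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.tif")) + sorted(p.glob("*.tiff"))
        if not files:
            raise FileNotFoundError(f"no .tif/.tiff files in {p}")
        slices = [tifffile.imread(f) for f in files]
        stack = np.stack(slices, axis=0)  # (z, y, x)
    else:
        stack = tifffile.imread(str(p))
        if stack.ndim == 2:
            stack = stack[None]
    return Volume(stack.transpose(2, 1, 0), (1.0, 1.0, 1.0))


def _write_tiff_stack(volume: Volume, path) -> None:
    import tifffile

    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    stack = np.asarray(volume.data).transpose(2, 1, 0)
    width = len(str(stack.shape[0]))
    for i, sl in enumerate(stack):
        tifffile.imwrite(p / f"slice_{i:0{width}d}.tif", sl)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def crop(volume: Volume, box: BoundingBox) -> Volume:
    """Crop to ``box``, shifting origin so physical coordinates are unchanged."""
    if any(h > s for h, s in zip(box.hi, volume.shape)):
        raise ValueError(f"bounding box {box} exceeds grid {volume.shape}")
    sub = volume.data[box.slices()]
    origin = tuple(
        o + l * s for o, l, s in zip(volume.origin, box.lo, volume.spacing)
    )
    return Volume(sub.copy(), volume.spacing, origin)


def binarize(volume: Volume, threshold: float) -> Volume:
    """Mask = 1 where intensity >= threshold."""
    return Volume(
        (np.asarray(volume.data) >= threshold).astype(np.uint8),
        volume.spacing,
        volume.origin,
    )


def split_bone_teeth(volume: Volume, bone_threshold: float = 500.0,
                     tooth_threshold: float = 900.0) -> tuple[Volume, Volume]:
    """Split a grayscale volume into (bone mask, tooth mask) by two thresholds.

    Teeth render brighter than bone (phantom contract); voxels at or above
    ``tooth_threshold`` are teeth, the rest at or above ``bone_threshold``
    are bone.
    """
    data = np.asarray(volume.data)
    tooth = data >= tooth_threshold
    bone = (data >= bone_threshold) & ~tooth
    return (
        Volume(bone.astype(np.uint8), volume.spacing, volume.origin),
        Volume(tooth.astype(np.uint8), volume.spacing, volume.origin),
    )


def extract_surface(mask: Volume) -> Volume:
    """Surface voxels: mask voxels with at least one 6-connected background
    neighbor (voxels on the grid boundary count as touching background)."""
    m = np.asarray(mask.data) > 0
    interior = ndimage.binary_erosion(m, structure=_six_connected(), border_value=0)
    return Volume((m & ~interior).astype(np.uint8), mask.spacing, mask.origin)


def _six_connected() -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1)


def connected_components(mask: Volume, connectivity: int = 1):
    """Label connected components; returns (label Volume, count).

    ``connectivity``: 1 for 6-connected, 3 for 26-connected.
    """
    labels, n = ndimage.label(
        np.asarray(mask.data) > 0, structure=ndimage.generate_binary_structure(3, connectivity)
    )
    return Volume(labels, mask.spacing, mask.origin), int(n)


def largest_component(mask: Volume, connectivity: int = 1) -> Volume:
    labels, n = connected_components(mask, connectivity)
    if n == 0:
        raise ValueError("empty mask has no components")
    counts = np.bincount(labels.data.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    return Volume((labels.data == keep).astype(np.uint8), mask.spacing, mask.origin)
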