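"""Volumetric containers, NIfTI I/O and volume measures.

PET images are held as 3-D grids of SUV (standardised uptake value, g/ml)
with per-axis voxel spacing in mm.  Conventions used throughout the
package:

* voxel indices are 0-based and a voxel's value represents its centre;
* axis 2 is the superior-inferior axis, so an "axial slice" is a fixed
  index along axis 2;
* axis 0 plays the role of the left-right axis, so a "sagittal slice"
  (the plane the MRI-style reference volume is measured on) is a fixed
  index along axis 0.

Label volumes use the integer codes below; the tumour label includes any
necrotic core, so reference volumes computed from it automatically count
central necrosis as tumour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BACKGROUND_LABEL",
    "TUMOUR_LABEL",
    "BLADDER_LABEL",
    "OTHER_LABEL",
    "ScalarVolume",
    "LabelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "mtv_ml",
    "reference_mri_volume",
]

BACKGROUND_LABEL = 0
TUMOUR_LABEL = 1
BLADDER_LABEL = 2
OTHER_LABEL = 3

_VALID_LABELS = frozenset({BACKGROUND_LABEL, TUMOUR_LABEL, BLADDER_LABEL, OTHER_LABEL})


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have three components, got {spacing!r}")
    if any((not np.isfinite(s)) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive and finite, got {spacing!r}")
    return spacing


def _check_origin(origin) -> tuple[float, float, float]:
    origin = tuple(float(o) for o in origin)
    if len(origin) != 3 or any(not np.isfinite(o) for o in origin):
        raise ValueError(f"origin must be three finite numbers, got {origin!r}")
    return origin


class _Grid:
    """Shared geometry helpers for aligned volumes (axis-aligned affine)."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self._array().shape

    def _array(self) -> np.ndarray:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_mm(self, index) -> np.ndarray:
        return np.asarray(self.origin, float) + np.asarray(index, float) * np.asarray(self.spacing, float)

    def mm_to_voxel(self, point) -> tuple[int, int, int]:
        """Nearest voxel index to a point in mm (clipped to the grid)."""
        idx = (np.asarray(point, float) - np.asarray(self.origin, float)) / np.asarray(self.spacing, float)
        idx = np.round(idx).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def axes_mm(self):
        """Per-axis voxel-centre coordinates as broadcastable open grids."""
        out = []
        for ax, (n, sp, o) in enumerate(zip(self.shape, self.spacing, self.origin)):
            c = o + sp * np.arange(n)
            shp = [1, 1, 1]
            shp[ax] = n
            out.append(c.reshape(shp))
        return tuple(out)


@dataclass
class ScalarVolume(_Grid):
    """3-D SUV grid with voxel spacing and origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"ScalarVolume requires a 3-D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ScalarVolume values must be finite")
        self.spacing = _check_spacing(self.spacing)
        self.origin = _check_origin(self.origin)

    def _array(self) -> np.ndarray:
        return self.values


@dataclass
class LabelVolume(_Grid):
    """Integer label grid aligned voxel-for-voxel with a ScalarVolume.

    Codes: 0 background, 1 tumour (incl. necrotic core), 2 bladder,
    3 other physiologic structure (bowel/ureter).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelVolume requires an integer grid")
        if self.labels.ndim != 3:
            raise ValueError(f"LabelVolume requires a 3-D grid, got ndim={self.labels.ndim}")
        codes = set(np.unique(self.labels).tolist())
        if not codes <= _VALID_LABELS:
            raise ValueError(f"unknown label codes {sorted(codes - _VALID_LABELS)}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = _check_origin(self.origin)

    def _array(self) -> np.ndarray:
        return self.labels

    def mask(self, label: int) -> "BinaryMask":
        return BinaryMask(self.labels == label, self.spacing, self.origin)

    @property
    def tumour(self) -> "BinaryMask":
        return self.mask(TUMOUR_LABEL)

    @property
    def bladder(self) -> "BinaryMask":
        return self.mask(BLADDER_LABEL)


@dataclass
class BinaryMask(_Grid):
    """Boolean voxel set aligned with a ScalarVolume (a VOI)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"BinaryMask requires a 3-D grid, got ndim={self.voxels.ndim}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = _check_origin(self.origin)

    def _array(self) -> np.ndarray:
        return self.voxels

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


def write_volume(vol: ScalarVolume | LabelVolume | BinaryMask, path) -> Path:
    """Write a volume as NIfTI-1; masks are stored as uint8 0/1."""
    path = Path(path)
    if isinstance(vol, ScalarVolume):
        data = np.asarray(vol.values, dtype=np.float64)
    elif isinstance(vol, LabelVolume):
        data = np.asarray(vol.labels, dtype=np.int16)
    elif isinstance(vol, BinaryMask):
        data = vol.voxels.astype(np.uint8)
    else:
        raise TypeError(f"cannot write object of type {type(vol).__name__}")
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path, kind: str = "auto") -> ScalarVolume | LabelVolume | BinaryMask:
    """Read a NIfTI-1 volume.

    ``kind`` is one of ``"auto"`` (integer on-disk dtype yields a
    LabelVolume, floating point a ScalarVolume), ``"scalar"``,
    ``"labels"`` or ``"mask"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path} is not a 3-D image (ndim={img.ndim})")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path} declares non-positive voxel spacing {spacing}")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    if kind == "auto":
        kind = "labels" if np.issubdtype(data.dtype, np.integer) else "scalar"
    if kind == "scalar":
        return ScalarVolume(np.asarray(data, float), spacing, origin)
    if kind == "labels":
        return LabelVolume(np.asarray(data).astype(np.int64), spacing, origin)
    if kind == "mask":
        return BinaryMask(np.asarray(data) != 0, spacing, origin)
    raise ValueError(f"unknown kind {kind!r}")


def mtv_ml(mask: BinaryMask | np.ndarray, spacing=None) -> float:
    """Metabolic tumour volume of a VOI in ml (voxel count x voxel volume)."""
    if isinstance(mask, BinaryMask):
        voxels = mask.voxels
        if spacing is None:
            spacing = mask.spacing
    else:
        voxels = np.asarray(mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing is required when mask is a bare array")
    dx, dy, dz = _check_spacing(spacing)
    return float(voxels.sum()) * dx * dy * dz / 1000.0


def reference_mri_volume(
    truth: LabelVolume | BinaryMask,
    slice_axis: int = 0,
    slice_thickness: float = 5.0,
    tumour_label: int = TUMOUR_LABEL,
) -> float:
    """MRI-style slice-summation tumour volume in ml.

    Emulates the radiologist's reference measurement: one tumour
    cross-sectional area is contoured per thick slice, multiplied by the
    slice thickness, and the per-slice volumes are summed.
    ``slice_thickness`` (default 5 mm, the MRI protocol value) must be an
    integer multiple of the native spacing along ``slice_axis``; native
    slices are aggregated into slabs whose representative area is taken
    from the central native slice (the mean of the two central slices
    when the multiple is even) - a midpoint rule that is exact for slabs
    aligned with slice boundaries and converges to the voxel-summation
    volume as the thickness approaches the native spacing.  Necrotic
    interior voxels carry the tumour label and are therefore included.
    """
    if isinstance(truth, LabelVolume):
        tum = truth.labels == tumour_label
    else:
        tum = truth.voxels
    if not tum.any():
        raise ValueError("no tumour voxels in the reference label volume")
    if slice_axis not in (0, 1, 2):
        raise ValueError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    native = truth.spacing[slice_axis]
    ratio = float(slice_thickness) / native
    m = int(round(ratio))
    if m < 1 or abs(ratio - m) > 1e-6:
        raise ValueError(
            f"slice_thickness {slice_thickness} mm is not an integer multiple "
            f"of the native spacing {native} mm along axis {slice_axis}"
        )
    arr = np.moveaxis(tum, slice_axis, 0)
    n = arr.shape[0]
    n_slabs = -(-n // m)
    if n_slabs * m != n:
        pad = np.zeros((n_slabs * m - n,) + arr.shape[1:], dtype=bool)
        arr = np.concatenate([arr, pad], axis=0)
    slabs = arr.reshape(n_slabs, m, *arr.shape[1:])
    central = [(m - 1) // 2] if m % 2 == 1 else [m // 2 - 1, m // 2]
    other = [truth.spacing[a] for a in (0, 1, 2) if a != slice_axis]
    pixel_area_mm2 = other[0] * other[1]
    areas = slabs[:, central].sum(axis=(2, 3)).mean(axis=1) * pixel_area_mm2
    return float(areas.sum() * slice_thickness / 1000.0)
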