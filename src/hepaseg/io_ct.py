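"""NIfTI volume I/O and slice plumbing.

Conventions
-----------
* Volumes are kept in the array layout nibabel hands back: axis order
  ``(x, y, z)`` with the axial (slice) axis last by default.  Within a 2D
  slice we index ``(row, col)``; indices are 0-based.
* Intensities are Hounsfield units and are never rescaled at read time.
* Masks are unsigned 8-bit with values in ``{0, 1}``.  Multi-label inputs
  (e.g. a combined annotation where 1 = liver, 2 = tumor) are split with
  :func:`split_labels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "CTVolume",
    "BinaryMask",
    "SliceImage",
    "ResampleRecord",
    "FormatError",
    "read_volume",
    "read_mask",
    "split_labels",
    "write_volume",
    "write_mask",
    "extract_slices",
    "stack_slices",
    "resize_slice",
    "resize_image",
    "invert_resize",
]


class FormatError(ValueError):
    """Raised for files that are readable but not a 3D scalar volume."""


@dataclass
class CTVolume:
    """A 3D CT scalar field in Hounsfield units.

    ``voxels`` has axis order (x, y, z); ``axial_axis`` names the slice
    axis (2 for the usual axial stack).  ``affine`` is the NIfTI voxel-to-
    world matrix and is carried along so outputs can be written aligned
    with their input.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.voxels.size == 0:
            raise ValueError("empty voxel grid")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("non-finite HU values in volume")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.axial_axis]


@dataclass
class BinaryMask:
    """Per-voxel {0,1} labels on the grid of a parent :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly {{0,1}}, found {vals}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def sum(self) -> int:
        return int(self.voxels.sum())


@dataclass
class SliceImage:
    """One 2D axial slice with provenance back to its volume."""

    pixels: np.ndarray
    volume_id: str = ""
    index: int = -1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ResampleRecord:
    """Everything needed to invert a slice resize."""

    source_shape: tuple[int, int]
    target_shape: tuple[int, int]
    order: int


def _check_nifti(img: nib.spatialimages.SpatialImage, path: Path) -> np.ndarray:
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 else data
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {data.shape}")
    return data


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI-1/2 CT volume; HU values are passed through unmodified."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = _check_nifti(img, path).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=data, spacing=spacing, affine=np.asarray(img.affine))


def read_mask(path: str | Path, ref: CTVolume | None = None) -> BinaryMask:
    """Read a binary label volume; any nonzero label is coerced to 1.

    A warning is emitted when labels other than {0,1} are found (LiTS-style
    annotations use 2 for tumor inside liver; use :func:`split_labels` when
    the distinction matters).
    """
    vol = read_volume(path)
    data = vol.voxels
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        warnings.warn(
            f"{path}: labels {vals} coerced to binary (nonzero -> 1)", stacklevel=2
        )
    mask = BinaryMask(
        (data != 0).astype(np.uint8), spacing=vol.spacing, affine=vol.affine
    )
    if ref is not None and mask.shape != ref.shape:
        raise ValueError(f"mask shape {mask.shape} != reference shape {ref.shape}")
    return mask


def split_labels(label_volume: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a combined {0,1,2} annotation into liver and tumor masks.

    Label 1 is liver tissue and label 2 is tumor inside the liver, so the
    liver envelope is {1,2} and the tumor mask is {2}.
    """
    lab = np.asarray(label_volume)
    liver = np.isin(lab, (1, 2)).astype(np.uint8)
    tumor = (lab == 2).astype(np.uint8)
    return liver, tumor


def write_volume(vol: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, ref: CTVolume, path: str | Path) -> None:
    """Write a mask with header geometry copied from its reference volume."""
    if mask.shape != ref.shape:
        raise ValueError(f"mask shape {mask.shape} != reference shape {ref.shape}")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), ref.affine)
    img.header.set_zooms(ref.spacing)
    nib.save(img, str(path))


def extract_slices(vol: CTVolume, volume_id: str = "") -> list[SliceImage]:
    """Split a volume into axial slices, ascending slice index."""
    moved = np.moveaxis(vol.voxels, vol.axial_axis, 0)
    return [
        SliceImage(pixels=moved[k], volume_id=volume_id, index=k)
        for k in range(moved.shape[0])
    ]


def stack_slices(
    slices: Sequence[SliceImage] | Sequence[np.ndarray], axial_axis: int = 2
) -> np.ndarray:
    """Reassemble axial slices into a volume (inverse of extract_slices)."""
    arrs = [s.pixels if isinstance(s, SliceImage) else np.asarray(s) for s in slices]
    return np.moveaxis(np.stack(arrs, axis=0), 0, axial_axis)


def resize_image(
    pixels: np.ndarray, target: tuple[int, int], order: int
) -> np.ndarray:
    """Resize a 2D array; bilinear (order 1) for intensities, nearest
    (order 0) for masks."""
    if min(target) < 8:
        raise ValueError(f"degenerate resize target {target}")
    if tuple(pixels.shape) == tuple(target):
        return pixels.copy()
    out = _sk_resize(
        pixels.astype(np.float32),
        target,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(pixels.dtype) if order == 0 else out.astype(np.float32)


def resize_slice(
    s: SliceImage, target: tuple[int, int], order: int = 1
) -> tuple[SliceImage, ResampleRecord]:
    out = resize_image(s.pixels, target, order)
    rec = ResampleRecord(
        source_shape=tuple(s.pixels.shape), target_shape=tuple(target), order=order
    )
    return SliceImage(pixels=out, volume_id=s.volume_id, index=s.index), rec


def invert_resize(pixels: np.ndarray, rec: ResampleRecord, order: int | None = None) -> np.ndarray:
    """Map a (possibly modified) resized slice back to its source grid."""
    if order is None:
        order = rec.order
    return resize_image(pixels, rec.source_shape, order)
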