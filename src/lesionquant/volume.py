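"""In-memory volume model and NIfTI-1 I/O.

A :class:`Volume` is a 3D scalar grid plus its voxel spacing in mm. The axis
convention is fixed: the first two axes are the in-plane (axial) rows and
columns, the third axis indexes slices. On load, images are reoriented to the
closest canonical (RAS) orientation so "slice" always means axis 2; the
affine of the canonical image is kept for write-back.

Masks (:class:`BinaryMask`) and network outputs (:class:`ProbabilityMap`) are
volumes with restricted value ranges, enforced at construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "ProbabilityMap",
    "read_volume",
    "write_volume",
    "as_binary_mask",
]


@dataclasses.dataclass
class Volume:
    """3D scalar image with voxel spacing in mm (axial slices along axis 2)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None  # retained from file for write-back

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if self.data.shape[2] < 1:
            raise ValueError("volume must contain at least one slice")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray, spacing=None) -> "Volume":
        """New volume of the same class carrying ``data`` (spacing optionally replaced)."""
        return type(self)(data, self.spacing if spacing is None else spacing, self.affine)

    def copy(self) -> "Volume":
        return type(self)(self.data.copy(), self.spacing, self.affine)


class BinaryMask(Volume):
    """Volume restricted to {0, 1}; brain or lesion mask."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)


class ProbabilityMap(Volume):
    """Volume of per-voxel memberships in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability map values must lie in [0, 1]")


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 image, reoriented to canonical axial order.

    Spacing is taken from the header zooms. Non-3D images and non-finite
    voxel values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"non-3D image ({len(img.shape)}D): {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, affine=np.asarray(img.affine))


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; masks are stored as unsigned 8-bit."""
    path = Path(path)
    if isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    else:
        data = np.asarray(v.data, dtype=np.float64)
    if v.affine is not None:
        affine = v.affine
    else:
        affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def as_binary_mask(v: Volume, tol: float = 1e-3) -> BinaryMask:
    """Snap a near-binary volume (e.g. a loaded manual annotation) to {0, 1}.

    Every voxel must lie within ``tol`` of 0 or of 1; anything else raises,
    which catches accidentally passing an intensity image as a mask.
    """
    data = np.asarray(v.data, dtype=np.float64)
    near0 = np.abs(data) <= tol
    near1 = np.abs(data - 1.0) <= tol
    if not np.all(near0 | near1):
        bad = data[~(near0 | near1)]
        raise ValueError(
            f"{bad.size} voxel(s) not within {tol} of 0 or 1 (e.g. {bad.flat[0]:g})"
        )
    return BinaryMask(near1.astype(np.uint8), v.spacing, v.affine)
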