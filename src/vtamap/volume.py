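"""3-D scalar volumes and binary masks on a regular voxel grid.

The pipeline consumes already-coregistered images: every stage requires
its inputs to share shape and voxel size, and raises
:class:`~vtamap.errors.DimensionError` otherwise. Files are read and
written as NIfTI-1 via nibabel with a diagonal affine built from the
voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import DimensionError

__all__ = ["VolumeGrid", "Mask", "check_same_grid"]


def _as_voxel_size(voxel_size_mm) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size_mm)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise DimensionError(f"voxel_size_mm must be 3 positive reals, got {voxel_size_mm!r}")
    return vs


@dataclass
class VolumeGrid:
    """A 3-D scalar field with physical voxel dimensions in mm."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise DimensionError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def save(self, path) -> None:
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path, id: str = "") -> "VolumeGrid":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), tuple(zooms), id=id)


@dataclass
class Mask:
    """A binary field on the same grid contract as :class:`VolumeGrid`."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise DimensionError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def save(self, path) -> None:
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path, id: str = "") -> "Mask":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.get_fdata()) > 0.5, tuple(zooms), id=id)


def check_same_grid(*grids) -> None:
    """Raise DimensionError unless all volumes/masks share shape and voxel size."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise DimensionError(f"shape mismatch: {g.shape} vs {ref.shape}")
        if not np.allclose(g.voxel_size_mm, ref.voxel_size_mm):
            raise DimensionError(
                f"voxel size mismatch: {g.voxel_size_mm} vs {ref.voxel_size_mm}"
            )
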