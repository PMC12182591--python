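"""In-memory containers for 3-D scalar volumes and binary ROI masks.

Conventions: voxel indices are 0-based, the ``affine`` maps homogeneous voxel
indices to RAS+ world coordinates in millimetres (the NIfTI convention), and
each volume carries a free-form ``space`` label ("template", "t1", "gre", ...)
used to validate transform chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "grids_match"]


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary signal units.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS+, mm) mapping.
    space : str
        Coordinate-space label used for transform-chain validation.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine has a singular linear part")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data))

    @classmethod
    def from_nifti(cls, path, space: str = "native") -> "ImageVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine, space)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine), str(path))


@dataclass
class RoiMask:
    """A binary 3-D region of interest aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    @classmethod
    def from_nifti(cls, path, space: str = "native") -> "RoiMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()) > 0.5, img.affine, space)

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))


def grids_match(a, b, atol: float = 1e-6) -> bool:
    """True when two volumes/masks share shape and voxel-to-world affine."""
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)
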