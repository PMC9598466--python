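"""Volumetric image container with world-coordinate (mm) awareness.

A :class:`Volume` is a 3D scalar array plus a 4x4 voxel-to-world affine,
mirroring the NIfTI convention used by nibabel.  All registration and
anonymization operators in this package consume and produce Volumes, so
voxel indexing never leaks past this module.
"""
from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class Volume:
    """3D scalar image with a voxel-to-world affine in mm."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    # -- grid geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Length of each voxel edge in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def grid_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack(idx, axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(*self.shape, 3)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    # -- sampling ------------------------------------------------------
    def sample(
        self, world_pts: np.ndarray, order: int = 1, cval: float = 0.0
    ) -> np.ndarray:
        """Interpolate the volume at world-space points (mm)."""
        vox = self.world_to_voxel(world_pts)
        return map_coordinates(
            self.data.astype(float, copy=False),
            vox.T,
            order=order,
            mode="constant",
            cval=cval,
        )

    def contains_world(self, world_pts: np.ndarray) -> np.ndarray:
        """True where points fall inside the voxel grid."""
        vox = self.world_to_voxel(world_pts)
        upper = np.array(self.shape, dtype=float) - 1.0
        return np.all((vox >= 0.0) & (vox <= upper), axis=1)

    # -- misc ----------------------------------------------------------
    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype), self.affine.copy())

    # -- I/O -----------------------------------------------------------
    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(float), img.affine)


def bool_volume(mask: np.ndarray, affine: np.ndarray) -> Volume:
    """Convenience constructor for boolean mask volumes."""
    return Volume(np.asarray(mask, dtype=bool), affine)
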