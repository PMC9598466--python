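"""Dense displacement fields mapping template space to subject space.

A :class:`DeformationField` stores per-voxel displacement vectors (mm)
on the template grid, so the warp is phi(x) = x + u(x) with x a template
world coordinate and phi(x) the corresponding subject world coordinate.
The numerical inverse (subject -> template displacement, sampled on the
same grid) is computed by fixed-point iteration and cached, so volumes
can be resampled in either direction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume


def _sample_field(disp: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinear sample of a (X,Y,Z,3) field at fractional voxel coords."""
    out = np.empty((len(vox), 3))
    for c in range(3):
        out[:, c] = map_coordinates(
            disp[..., c], vox.T, order=1, mode="nearest"
        )
    return out


@dataclass
class DeformationField:
    """Template-to-subject displacement (mm) on the template grid."""

    displacement: np.ndarray  # (X, Y, Z, 3) in mm
    affine: np.ndarray  # template voxel -> world
    _inverse: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must have shape (X, Y, Z, 3)")

    # -- constructors --------------------------------------------------
    @classmethod
    def identity(cls, shape: tuple[int, int, int], affine: np.ndarray):
        return cls(np.zeros((*shape, 3)), affine)

    # -- geometry helpers ----------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def _world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return np.atleast_2d(xyz) @ inv[:3, :3].T + inv[:3, 3]

    def grid_world(self) -> np.ndarray:
        idx = np.stack(np.indices(self.shape, dtype=float), axis=-1).reshape(-1, 3)
        return (idx @ self.affine[:3, :3].T + self.affine[:3, 3]).reshape(
            *self.shape, 3
        )

    def contains_world(self, world_pts: np.ndarray) -> np.ndarray:
        vox = self._world_to_voxel(world_pts)
        upper = np.array(self.shape, dtype=float) - 1.0
        return np.all((vox >= 0.0) & (vox <= upper), axis=1)

    # -- sampling ------------------------------------------------------
    def sample(self, world_pts: np.ndarray) -> np.ndarray:
        """Forward displacement u(x) at world points (template space)."""
        pts = np.atleast_2d(np.asarray(world_pts, dtype=float))
        return _sample_field(self.displacement, self._world_to_voxel(pts))

    def sample_inverse(self, world_pts: np.ndarray) -> np.ndarray:
        """Inverse displacement at world points (subject space)."""
        pts = np.atleast_2d(np.asarray(world_pts, dtype=float))
        return _sample_field(self.inverse_displacement, self._world_to_voxel(pts))

    def map_points(self, world_pts: np.ndarray) -> np.ndarray:
        """phi(x): template -> subject."""
        pts = np.atleast_2d(np.asarray(world_pts, dtype=float))
        return pts + self.sample(pts)

    def unmap_points(self, world_pts: np.ndarray) -> np.ndarray:
        """phi^{-1}(y): subject -> template (numerical inverse)."""
        pts = np.atleast_2d(np.asarray(world_pts, dtype=float))
        return pts + self.sample_inverse(pts)

    # -- inverse -------------------------------------------------------
    @property
    def inverse_displacement(self) -> np.ndarray:
        if self._inverse is None:
            self._inverse = self._compute_inverse()
        return self._inverse

    def _compute_inverse(self, n_iter: int = 40) -> np.ndarray:
        """Fixed-point inversion: v(y) = -u(y + v(y)), iterated on the grid."""
        grid = self.grid_world().reshape(-1, 3)
        v = np.zeros_like(grid)
        for _ in range(n_iter):
            v_new = -self.sample(grid + v)
            if np.max(np.abs(v_new - v)) < 1e-4:
                v = v_new
                break
            v = v_new
        return v.reshape(*self.shape, 3)

    def inverse_consistency_residual(self) -> float:
        """Mean |phi^{-1}(phi(x)) - x| over the grid, in voxels."""
        grid = self.grid_world().reshape(-1, 3)
        fwd = grid + self.displacement.reshape(-1, 3)
        back = fwd + self.sample_inverse(fwd)
        res_mm = np.linalg.norm(back - grid, axis=1)
        return float(res_mm.mean() / self.voxel_size.mean())

    # -- differential --------------------------------------------------
    def jacobian_determinant(self) -> np.ndarray:
        """det of d(phi)/dx at every voxel (phi = id + u, world mm units)."""
        # displacement gradient in world units: chain rule through the affine
        M_inv = np.linalg.inv(self.affine[:3, :3])
        grads = []
        for c in range(3):
            g = np.stack(np.gradient(self.displacement[..., c]), axis=-1)
            grads.append(g @ M_inv)  # d u_c / d world
        J = np.stack(grads, axis=-2)  # (..., 3, 3) rows: du_c/dx
        J = J + np.eye(3)
        return np.linalg.det(J)

    # -- I/O -----------------------------------------------------------
    def save(self, path) -> None:
        img = nib.Nifti1Image(self.displacement.astype(np.float32), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "DeformationField":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(float), img.affine)


def pull_to_template(subject: Volume, fld: DeformationField, order: int = 1) -> Volume:
    """Resample a subject-space volume onto the template grid.

    out(x) = subject(x + u(x)) — the template-grid view of the subject.
    """
    pts = fld.grid_world().reshape(-1, 3)
    warped = subject.sample(pts + fld.displacement.reshape(-1, 3), order=order)
    return Volume(warped.reshape(fld.shape), fld.affine.copy())


def push_to_subject(template: Volume, fld: DeformationField, order: int = 1) -> Volume:
    """Resample a template-space volume into subject space (same grid).

    out(y) = template(phi^{-1}(y)), using the cached numerical inverse.
    """
    pts = fld.grid_world().reshape(-1, 3)
    warped = template.sample(
        pts + fld.inverse_displacement.reshape(-1, 3), order=order
    )
    return Volume(warped.reshape(fld.shape), fld.affine.copy())
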