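"""Subject-template registration and atlas-based tissue labeling.

Joint segmentation-registration machinery (SPM's Unified Segmentation)
is deliberately replaced by a sequential pipeline with the same
contract: a 12-dof intensity-driven affine, a multi-resolution
demons-style small-deformation registration with Gaussian smoothness
regularization, and trilinear warping of the tissue probability map
(including the face-without-nose class) into subject space.  The output
— a per-class probability volume in subject space — is all the
anonymization step needs.
"""
from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter, map_coordinates

from .deformation import DeformationField
from .volume import Volume


class RegistrationDivergence(RuntimeError):
    """Raised when the registration objective increases persistently."""


# ---------------------------------------------------------------------
# affine registration
# ---------------------------------------------------------------------

def _affine_from_params(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12-dof affine: translation, rotation (deg), log-scale and shear
    (both in percent units), composed about ``center``."""
    t = p[0:3]
    rx, ry, rz = np.radians(p[3:6])
    scale = np.exp(p[6:9] / 100.0)
    shear = p[9:12] / 100.0
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(scale)
    H = np.array([[1, shear[0], shear[1]], [0, 1, shear[2]], [0, 0, 1]])
    M = Rz @ Ry @ Rx @ S @ H
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = t + center - M @ center
    return A


def _world_bbox(vol: Volume) -> tuple[np.ndarray, np.ndarray]:
    corners = np.array(
        [[i, j, k] for i in (0, vol.shape[0] - 1)
         for j in (0, vol.shape[1] - 1)
         for k in (0, vol.shape[2] - 1)],
        dtype=float,
    )
    world = vol.voxel_to_world(corners)
    return world.min(axis=0), world.max(axis=0)


def affine_register(
    subject: Volume,
    template: Volume,
    levels: tuple[int, ...] = (4, 2, 1),
    smooth_sigma_vox: tuple[float, ...] = (2.0, 1.0, 0.5),
    maxiter: int = 60,
) -> np.ndarray:
    """Estimate the 12-dof template-to-subject world affine.

    Minimizes the sum of squared intensity differences between the
    template and the subject resampled through the affine, coarse to
    fine over a strided pyramid, by Powell search on a scaled parameter
    vector.  Returns a 4x4 matrix ``A`` such that
    ``subject(A(x)) ~= template(x)`` for template world coordinates x.
    """
    if float(np.std(subject.data)) < 1e-9 or float(np.std(template.data)) < 1e-9:
        raise ValueError("cannot register constant images")
    lo_s, hi_s = _world_bbox(subject)
    lo_t, hi_t = _world_bbox(template)
    if np.any(hi_s < lo_t) or np.any(hi_t < lo_s):
        raise ValueError("subject and template fields of view do not overlap")

    weights = np.abs(template.data)
    total = weights.sum()
    if total <= 0:
        raise ValueError("template has no signal")
    com_vox = np.array(
        [np.sum(weights * g) for g in np.indices(template.shape)]
    ) / total
    center = template.voxel_to_world(com_vox)[0]

    p = np.zeros(12)
    for stride, sigma in zip(levels, smooth_sigma_vox):
        tpl = gaussian_filter(template.data.astype(float), max(sigma, stride / 2.0))
        tpl_small = tpl[::stride, ::stride, ::stride]
        aff_small = template.affine.copy()
        aff_small[:3, :3] *= stride
        small = Volume(tpl_small, aff_small)
        pts = small.grid_world().reshape(-1, 3)
        tpl_vals = tpl_small.reshape(-1)
        subj_s = Volume(
            gaussian_filter(subject.data.astype(float), max(sigma, stride / 2.0)),
            subject.affine,
        )

        def cost(params: np.ndarray) -> float:
            A = _affine_from_params(params, center)
            vals = subj_s.sample(pts @ A[:3, :3].T + A[:3, 3])
            return float(np.mean((vals - tpl_vals) ** 2))

        res = optimize.minimize(
            cost, p, method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-9},
        )
        p = res.x
    return _affine_from_params(p, center)


# ---------------------------------------------------------------------
# demons-style nonlinear registration
# ---------------------------------------------------------------------

def _resize_field(u: np.ndarray, new_shape: tuple[int, int, int]) -> np.ndarray:
    """Linear resize of a (X,Y,Z,3) voxel-unit field, rescaling vectors."""
    old_shape = np.array(u.shape[:3], dtype=float)
    new = np.array(new_shape, dtype=float)
    coords = np.indices(new_shape, dtype=float)
    scale = (old_shape - 1) / np.maximum(new - 1, 1)
    coords = coords * scale[:, None, None, None]
    out = np.empty((*new_shape, 3))
    for c in range(3):
        out[..., c] = map_coordinates(u[..., c], coords, order=1, mode="nearest")
        out[..., c] *= (new - 1)[c] / max(old_shape[c] - 1, 1)
    return out


def _downsample(data: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return data.astype(float)
    return gaussian_filter(data.astype(float), stride / 2.0)[::stride, ::stride, ::stride]


def _demons(
    fixed: np.ndarray,
    moving: np.ndarray,
    levels: tuple[int, ...],
    iterations: tuple[int, ...],
    sigma_fluid: float,
    sigma_elastic: float,
    step_max_vox: float,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Thirion-style demons on a pyramid; returns voxel-unit displacement
    on the full-resolution grid and the (start, end) energy per level."""
    u: np.ndarray | None = None
    energies: list[tuple[float, float]] = []
    for stride, n_iter in zip(levels, iterations):
        F = _downsample(fixed, stride)
        M = _downsample(moving, stride)
        if u is None:
            u = np.zeros((*F.shape, 3))
        elif u.shape[:3] != F.shape:
            u = _resize_field(u, F.shape)
        ident = np.indices(F.shape, dtype=float)

        def warp_energy(uu: np.ndarray) -> tuple[np.ndarray, float]:
            coords = ident + np.moveaxis(uu, -1, 0)
            W = map_coordinates(M, coords, order=1, mode="nearest")
            return W, float(np.mean((F - W) ** 2))

        _, e_start = warp_energy(u)
        if not np.isfinite(e_start):
            raise RegistrationDivergence("non-finite registration energy")
        # keep the best-energy state seen in the level: intensity
        # mismatch (e.g. a zeroed face region) can make late iterations
        # oscillate, and the level must never end worse than it began
        e_best, u_best = e_start, u.copy()
        for _ in range(n_iter):
            W, e_now = warp_energy(u)
            if e_now < e_best:
                e_best, u_best = e_now, u.copy()
            diff = F - W
            g = np.gradient(W)
            g2 = g[0] ** 2 + g[1] ** 2 + g[2] ** 2
            denom = g2 + diff**2
            upd = np.zeros_like(u)
            valid = denom > 1e-9
            for c in range(3):
                upd[..., c][valid] = (diff * g[c])[valid] / denom[valid]
            norm = np.linalg.norm(upd, axis=-1)
            over = norm > step_max_vox
            if over.any():
                upd[over] *= (step_max_vox / norm[over])[..., None]
            for c in range(3):
                upd[..., c] = gaussian_filter(upd[..., c], sigma_fluid)
                u[..., c] = gaussian_filter(u[..., c] + upd[..., c], sigma_elastic)
        _, e_last = warp_energy(u)
        if e_last < e_best:
            e_best, u_best = e_last, u
        u = u_best
        energies.append((e_start, e_best))
        if not np.isfinite(e_best) or e_best > e_start * (1.0 + 1e-9):
            raise RegistrationDivergence(
                f"energy increased at pyramid stride {stride}: "
                f"{e_start:.6g} -> {e_best:.6g}"
            )
    assert u is not None
    if u.shape[:3] != fixed.shape:
        u = _resize_field(u, fixed.shape)
    return u, energies


def nonlinear_register(
    subject: Volume,
    template: Volume,
    init_affine: np.ndarray | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    iterations: tuple[int, ...] = (60, 40, 15),
    sigma_fluid_vox: float = 1.0,
    sigma_elastic_vox: float = 1.0,
    step_max_vox: float = 0.8,
) -> DeformationField:
    """Small-deformation registration of a subject onto the template.

    Runs demons-style multi-resolution registration of the subject
    (optionally pre-aligned through ``init_affine``) against the
    template and returns the template-to-subject displacement field on
    the template grid, with per-level energies in
    ``field.level_energies`` (each level must not increase the energy;
    persistent increase raises :class:`RegistrationDivergence`).  The
    field's Jacobian is kept positive by extra smoothing if needed.
    """
    A = np.eye(4) if init_affine is None else np.asarray(init_affine, dtype=float)
    grid = Volume(np.zeros(template.shape), template.affine).grid_world()
    pts = grid.reshape(-1, 3)
    moving = subject.sample(pts @ A[:3, :3].T + A[:3, 3]).reshape(template.shape)

    u_vox, energies = _demons(
        np.asarray(template.data, dtype=float),
        moving,
        levels,
        iterations,
        sigma_fluid_vox,
        sigma_elastic_vox,
        step_max_vox,
    )
    # compose the demons field with the initial affine:
    # phi(x) = A(x + u_d(x));  displacement u(x) = phi(x) - x  (mm)
    M = template.affine[:3, :3]
    u_mm = u_vox.reshape(-1, 3) @ M.T
    phi = (pts + u_mm) @ A[:3, :3].T + A[:3, 3]
    disp = (phi - pts).reshape(*template.shape, 3)

    fld = DeformationField(disp, template.affine.copy())
    for _ in range(3):
        if fld.jacobian_determinant().min() > 0:
            break
        smoothed = np.stack(
            [gaussian_filter(fld.displacement[..., c], 1.0) for c in range(3)],
            axis=-1,
        )
        fld = DeformationField(smoothed, template.affine.copy())
    if fld.jacobian_determinant().min() <= 0:
        raise RegistrationDivergence("estimated field is not invertible")
    fld.level_energies = energies  # type: ignore[attr-defined]
    return fld


# ---------------------------------------------------------------------
# tissue labeling
# ---------------------------------------------------------------------

def label_tissues(subject: Volume, tpm, fld: DeformationField) -> dict[str, Volume]:
    """Warp the tissue probability map into subject space.

    ``tpm`` is a mapping of class name to probability Volume on the
    template grid (a :class:`~noseguard.phantom.TemplatePackage` is
    accepted as well).  Each class is pulled through the inverse
    deformation with trilinear interpolation — never nearest-neighbor,
    which would alias the downstream face-probability threshold — and
    the result is renormalized to sum to one per voxel.
    """
    classes = getattr(tpm, "tpm", tpm)
    names = list(classes)
    first = classes[names[0]]
    if first.shape != fld.shape or not np.allclose(first.affine, fld.affine):
        raise ValueError("deformation field and TPM are on different grids")

    pts = subject.grid_world().reshape(-1, 3)
    sample_at = pts + fld.sample_inverse(pts)
    warped = {}
    for name in names:
        vals = classes[name].sample(sample_at).reshape(subject.shape)
        warped[name] = np.clip(vals, 0.0, None)
    total = np.sum([warped[n] for n in names], axis=0)
    empty = total < 1e-6
    total[empty] = 1.0
    out = {}
    for name in names:
        prob = warped[name] / total
        if name == "background":
            prob[empty] = 1.0
        out[name] = Volume(prob, subject.affine.copy())
    return out
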