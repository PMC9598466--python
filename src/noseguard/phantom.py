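"""Synthetic head phantoms with known registration ground truth.

The generator builds a head-shaped template (superellipsoid head with a
protruding nose, ear bumps, and concentric skull/brain shells), a
tissue probability map that includes a dedicated face-without-nose
class, and a canonical inner-skull mesh.  Subjects are produced by
pushing the template through a random smooth, invertible deformation
plus intensity noise, so the template-to-subject field, the fiducials,
and the scalp/inner-skull surfaces are all known exactly — every
downstream registration or anonymization step can be scored against
ground truth without patient data.

Intensity model (arbitrary but fixed): air 0, soft tissue 0.7, skull
0.3, brain 1.0, with a smooth low-frequency modulation inside the brain
and scalp emulating grey/white and soft-tissue contrast (without it,
intensity-driven registration would have no signal inside otherwise
flat compartments).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .deformation import DeformationField, push_to_subject
from .geometry import HeadPointSet, RigidTransform, apply_transform
from .meshes import SurfaceMesh, extract_scalp, make_icosphere, warp_canonical_innerskull
from .volume import Volume, bool_volume

# ---------------------------------------------------------------------
# template geometry (world mm; head roughly centered on the origin)
# ---------------------------------------------------------------------
HEAD_CENTER = np.array([0.0, -8.0, 0.0])
HEAD_SEMI = np.array([60.0, 70.0, 65.0])
HEAD_EXPONENT = 2.5
NOSE_CENTER = np.array([0.0, 52.0, -18.0])
NOSE_SEMI = np.array([10.0, 26.0, 13.0])
EAR_CENTERS = np.array([[-60.0, -12.0, -8.0], [60.0, -12.0, -8.0]])
EAR_SEMI = np.array([9.0, 14.0, 14.0])
BRAIN_CENTER = np.array([0.0, -8.0, 6.0])
BRAIN_SEMI = np.array([45.0, 48.0, 50.0])
SKULL_SEMI = np.array([50.0, 54.0, 55.0])
FACE_SHELL_INNER = 0.80  # superellipsoid level set bounding the face shell depth
FACE_Y_MIN = 30.0
FACE_Z_MAX = 5.0  # face stops just above the nasion plane (brow line)
# standard de-facing removes a rectangular cuboid covering the face
# (nose included, cut running deep to the facial bones)
DEFACE_Y_MIN = 44.0
DEFACE_Z_MAX = 25.0  # the cut reaches above the eyes, as common de-facers do
FIDUCIALS_TEMPLATE = {
    "nasion": np.array([0.0, 62.0, 0.0]),  # nose-root midline on the head surface
    "lpa": np.array([-69.0, -12.0, -8.0]),  # lateral tip of the left ear bump
    "rpa": np.array([69.0, -12.0, -8.0]),
}
TISSUE_INTENSITY = {"soft_tissue": 0.7, "skull": 0.3, "brain": 1.0}
TPM_CLASSES = ("background", "soft_tissue", "skull", "brain", "face")
SCALP_THRESHOLD = 0.35  # half of the soft-tissue intensity
MARGIN_MM = 6.0  # clearance required between structures and the grid edge


@dataclass
class TemplatePackage:
    """Template volume, tissue probability map and canonical meshes."""

    template_volume: Volume
    tpm: dict[str, Volume]
    canonical_inner_skull: SurfaceMesh
    scalp: SurfaceMesh
    masks: dict[str, Volume]

    @property
    def affine(self) -> np.ndarray:
        return self.template_volume.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.template_volume.shape


@dataclass
class PhantomSubject:
    """A synthetic subject: template pushed through a known deformation."""

    volume: Volume
    brain_mask: Volume
    head_mask: Volume
    face_mask: Volume
    nose_mask: Volume
    fiducials_mri: HeadPointSet
    true_deformation: DeformationField
    true_scalp: SurfaceMesh
    true_inner_skull: SurfaceMesh

    def nose_bbox_world(self, pad_mm: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
        """World-space bounding box of the nose mask, padded."""
        if not self.nose_mask.data.any():
            raise ValueError("phantom has no nose voxels")
        idx = np.argwhere(self.nose_mask.data)
        world = self.nose_mask.voxel_to_world(idx.astype(float))
        return world.min(axis=0) - pad_mm, world.max(axis=0) + pad_mm


# ---------------------------------------------------------------------
# template
# ---------------------------------------------------------------------

def _superellipsoid(pts: np.ndarray, center, semi, exponent) -> np.ndarray:
    q = np.abs((pts - center) / semi) ** exponent
    return q.sum(axis=-1)


def _ellipsoid_mask(pts, center, semi) -> np.ndarray:
    return (((pts - center) / semi) ** 2).sum(axis=-1) <= 1.0


def make_template(
    grid_shape: tuple[int, int, int] = (52, 56, 48),
    voxel_size_mm: float = 3.0,
    seed: int = 0,
) -> TemplatePackage:
    """Build the synthetic head template with TPM and canonical meshes.

    Deterministic given ``seed`` (the seed fixes the phase of the
    intensity texture).  The head anatomy has a fixed physical size, so
    the grid must be large enough to contain it with a safety margin.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 48:
        raise ValueError("grid_shape must be 3 axes of at least 48 voxels")
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    extent = np.array(grid_shape) * voxel_size_mm
    required = 2 * np.array([69.0 + MARGIN_MM, 78.0 + MARGIN_MM, 65.0 + MARGIN_MM])
    if np.any(extent + 1e-9 < required):
        raise ValueError(
            f"grid too small to contain all structures: extent {extent} mm, "
            f"need at least {required} mm"
        )
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = -voxel_size_mm * (np.array(grid_shape) - 1) / 2.0

    vol0 = Volume(np.zeros(grid_shape), affine)
    pts = vol0.grid_world()

    head_base = _superellipsoid(pts, HEAD_CENTER, HEAD_SEMI, HEAD_EXPONENT) <= 1.0
    nose_ell = _ellipsoid_mask(pts, NOSE_CENTER, NOSE_SEMI)
    ear_l = _ellipsoid_mask(pts, EAR_CENTERS[0], EAR_SEMI)
    ear_r = _ellipsoid_mask(pts, EAR_CENTERS[1], EAR_SEMI)
    head = head_base | nose_ell | ear_l | ear_r
    nose = nose_ell & ~head_base  # the protruding part of the nose
    brain = _ellipsoid_mask(pts, BRAIN_CENTER, BRAIN_SEMI)
    skull = _ellipsoid_mask(pts, BRAIN_CENTER, SKULL_SEMI) & ~brain

    level = _superellipsoid(pts, HEAD_CENTER, HEAD_SEMI, HEAD_EXPONENT)
    shell = (level > FACE_SHELL_INNER) & head_base
    nose_guard = binary_dilation(nose_ell, iterations=2)
    # keep the face class clear of the brain so that smoothing and a
    # slightly imperfect warp can never push face probability over the
    # trimming threshold inside the brain
    brain_guard = binary_dilation(brain, iterations=3)
    face = (
        shell
        & (pts[..., 1] > FACE_Y_MIN)
        & (pts[..., 2] < FACE_Z_MAX)
        & ~nose_guard
        & ~ear_l
        & ~ear_r
        & ~brain_guard
        & ~skull
    )

    soft = head & ~brain & ~skull
    deface = head & (pts[..., 1] > DEFACE_Y_MIN) & (pts[..., 2] < DEFACE_Z_MAX)

    # intensities with low-frequency texture for registration contrast
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=6)
    tex_brain = (
        np.sin(2 * np.pi * pts[..., 0] / 41.0 + phase[0])
        * np.sin(2 * np.pi * pts[..., 1] / 47.0 + phase[1])
        * np.sin(2 * np.pi * pts[..., 2] / 37.0 + phase[2])
    )
    tex_soft = (
        np.sin(2 * np.pi * pts[..., 0] / 53.0 + phase[3])
        * np.sin(2 * np.pi * pts[..., 1] / 43.0 + phase[4])
        * np.sin(2 * np.pi * pts[..., 2] / 59.0 + phase[5])
    )
    data = np.zeros(grid_shape)
    data[soft] = TISSUE_INTENSITY["soft_tissue"] + 0.08 * tex_soft[soft]
    data[skull] = TISSUE_INTENSITY["skull"]
    data[brain] = TISSUE_INTENSITY["brain"] + 0.15 * tex_brain[brain]
    data = gaussian_filter(data, 0.7)
    template_volume = Volume(data, affine)

    # tissue probability map: hard labels softened by a small Gaussian,
    # renormalized, with the face class forced to zero on the nose
    labels = {
        "background": ~head,
        "soft_tissue": soft & ~face,
        "skull": skull,
        "brain": brain,
        "face": face,
    }
    tpm = {}
    for name in TPM_CLASSES:
        tpm[name] = gaussian_filter(labels[name].astype(float), 0.7)
    nose_region = binary_dilation(nose, iterations=1)
    tpm["face"][nose_region] = 0.0
    tpm["face"][binary_dilation(brain, iterations=2)] = 0.0
    total = np.sum([tpm[name] for name in TPM_CLASSES], axis=0)
    total[total < 1e-12] = 1.0
    tpm_vols = {
        name: Volume(tpm[name] / total, affine) for name in TPM_CLASSES
    }

    inner_skull = make_icosphere(4)
    inner_skull = SurfaceMesh(
        BRAIN_CENTER + inner_skull.vertices * (BRAIN_SEMI * 0.97), inner_skull.faces
    )
    scalp = extract_scalp(template_volume, SCALP_THRESHOLD)

    masks = {
        "head": bool_volume(head, affine),
        "brain": bool_volume(brain, affine),
        "skull": bool_volume(skull, affine),
        "soft_tissue": bool_volume(soft, affine),
        "face": bool_volume(face, affine),
        "nose": bool_volume(nose, affine),
        "deface": bool_volume(deface, affine),
    }
    return TemplatePackage(
        template_volume=template_volume,
        tpm=tpm_vols,
        canonical_inner_skull=inner_skull,
        scalp=scalp,
        masks=masks,
    )


# ---------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------

def _random_smooth_field(
    template: Volume, amplitude_mm: float, rng: np.random.Generator, n_modes: int = 6
) -> np.ndarray:
    """Band-limited random displacement built from low-order sinusoids."""
    pts = template.grid_world()
    lo = pts.reshape(-1, 3).min(axis=0)
    hi = pts.reshape(-1, 3).max(axis=0)
    xn = (pts - lo) / (hi - lo)
    u = np.zeros_like(pts)
    for c in range(3):
        comp = np.zeros(template.shape)
        for _ in range(n_modes):
            k = rng.integers(1, 3, size=3)
            phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
            weight = rng.normal()
            comp = comp + weight * (
                np.sin(np.pi * k[0] * xn[..., 0] + phase[0])
                * np.sin(np.pi * k[1] * xn[..., 1] + phase[1])
                * np.sin(np.pi * k[2] * xn[..., 2] + phase[2])
            )
        u[..., c] = comp
    peak = np.max(np.linalg.norm(u, axis=-1))
    if peak > 0:
        u *= amplitude_mm / peak
    return u


def make_head_phantom(
    template: TemplatePackage,
    deform_amplitude_mm: float = 4.0,
    seed: int = 0,
    intensity_noise_sd: float = 0.02,
    max_attempts: int = 5,
) -> PhantomSubject:
    """Generate a subject by deforming the template through a smooth field.

    The field is regenerated (up to ``max_attempts`` times) if its
    Jacobian determinant is not strictly positive on the grid; the
    numerical inverse must round-trip within 0.1 voxel.  All masks,
    fiducials and surfaces are carried through the same deformation, so
    they remain mutually consistent ground truth.
    """
    rng = np.random.default_rng(seed)
    tvol = template.template_volume
    if deform_amplitude_mm < 0:
        raise ValueError("deformation amplitude must be >= 0")

    fld = None
    for _ in range(max_attempts):
        if deform_amplitude_mm == 0:
            disp = np.zeros((*tvol.shape, 3))
        else:
            disp = _random_smooth_field(tvol, deform_amplitude_mm, rng)
        candidate = DeformationField(disp, tvol.affine.copy())
        if deform_amplitude_mm == 0:
            fld = candidate
            break
        if candidate.jacobian_determinant().min() <= 0.05:
            continue
        if candidate.inverse_consistency_residual() >= 0.1:
            continue
        fld = candidate
        break
    if fld is None:
        raise RuntimeError(
            f"could not generate an invertible field of amplitude "
            f"{deform_amplitude_mm} mm in {max_attempts} attempts"
        )

    subject_vol = push_to_subject(tvol, fld)
    if intensity_noise_sd > 0:
        subject_vol = Volume(
            subject_vol.data + rng.normal(0.0, intensity_noise_sd, tvol.shape),
            subject_vol.affine,
        )

    def warp_mask(name: str) -> Volume:
        warped = push_to_subject(template.masks[name].astype(float), fld)
        return bool_volume(warped.data > 0.5, warped.affine)

    fid_pts = np.stack([FIDUCIALS_TEMPLATE[k] for k in ("nasion", "lpa", "rpa")])
    fiducials = HeadPointSet(
        fld.map_points(fid_pts),
        np.array(["nasion", "lpa", "rpa"], dtype=object),
        frame="mri_world",
    )

    return PhantomSubject(
        volume=subject_vol,
        brain_mask=warp_mask("brain"),
        head_mask=warp_mask("head"),
        face_mask=warp_mask("face"),
        nose_mask=warp_mask("nose"),
        fiducials_mri=fiducials,
        true_deformation=fld,
        true_scalp=warp_canonical_innerskull(template.scalp, fld),
        true_inner_skull=warp_canonical_innerskull(template.canonical_inner_skull, fld),
    )


# ---------------------------------------------------------------------
# digitized point sets
# ---------------------------------------------------------------------

def _sample_on_faces(
    mesh: SurfaceMesh, face_idx: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    areas = mesh.triangle_areas()[face_idx]
    probs = areas / areas.sum()
    chosen = rng.choice(face_idx, size=n, p=probs)
    tri = mesh.vertices[mesh.faces[chosen]]
    r1 = np.sqrt(rng.uniform(size=n))
    r2 = rng.uniform(size=n)
    w = np.stack([1 - r1, r1 * (1 - r2), r1 * r2], axis=1)
    return np.einsum("nk,nkd->nd", w, tri)


def sample_head_points(
    subject: PhantomSubject,
    n_scalp: int = 100,
    n_nose: int = 10,
    noise_sd_mm: float = 0.0,
    device_transform: RigidTransform | None = None,
    seed: int = 0,
    fiducial_noise_sd_mm: float | None = None,
    scalp_z_min_mm: float = 10.0,
) -> HeadPointSet:
    """Digitize fiducials plus scalp and nose points from a phantom.

    Scalp points are sampled area-weighted on the upper head (above
    ``scalp_z_min_mm``, outside the nose region), nose points on the
    nose surface; isotropic Gaussian noise emulates digitizer error,
    and everything is mapped into device coordinates.  The noiseless
    mri_world source locations are retained on the returned set for
    ground-truth evaluation.  A default of ~100 scalp points matches
    common MEG practice.
    """
    if n_scalp + n_nose < 3:
        raise ValueError("need at least 3 sampled points")
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be >= 0")
    if fiducial_noise_sd_mm is None:
        fiducial_noise_sd_mm = noise_sd_mm
    rng = np.random.default_rng(seed)
    mesh = subject.true_scalp
    centroids = mesh.face_centroids()

    if n_nose > 0 and not subject.nose_mask.data.any():
        raise ValueError("nose points requested but phantom has no nose")
    nose_faces = np.array([], dtype=int)
    in_nose = np.zeros(len(centroids), dtype=bool)
    if subject.nose_mask.data.any():
        lo, hi = subject.nose_bbox_world()
        in_nose = np.all((centroids >= lo) & (centroids <= hi), axis=1)
        nose_faces = np.flatnonzero(in_nose)
    if n_nose > 0 and len(nose_faces) == 0:
        raise ValueError("no scalp faces found in the nose region")

    scalp_faces = np.flatnonzero((centroids[:, 2] > scalp_z_min_mm) & ~in_nose)
    if n_scalp > 0 and len(scalp_faces) == 0:
        raise ValueError("no scalp faces above the sampling plane")

    src, labels = [], []
    fid_true = subject.fiducials_mri.fiducial_array()
    for lab, pt in zip(("nasion", "lpa", "rpa"), fid_true):
        src.append(pt)
        labels.append(lab)
    if n_scalp > 0:
        src.extend(_sample_on_faces(mesh, scalp_faces, n_scalp, rng))
        labels.extend(["scalp"] * n_scalp)
    if n_nose > 0:
        src.extend(_sample_on_faces(mesh, nose_faces, n_nose, rng))
        labels.extend(["nose"] * n_nose)
    src = np.asarray(src)
    labels = np.asarray(labels, dtype=object)

    noisy = src.copy()
    noisy[:3] += rng.normal(0.0, fiducial_noise_sd_mm, (3, 3))
    if len(src) > 3:
        noisy[3:] += rng.normal(0.0, noise_sd_mm, (len(src) - 3, 3))

    if device_transform is None:
        device_transform = RigidTransform.identity()
    device_pts = device_transform.apply(noisy)
    return HeadPointSet(device_pts, labels, frame="device", source_points=src)
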