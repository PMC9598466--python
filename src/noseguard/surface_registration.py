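"""Head-point-to-scalp registration: exact surface distances, multi-start
ICP, and the two-step (fiducial initialization + ICP refinement)
MEG-MRI coregistration.

The upper head is nearly hemispherical, so ICP on scalp points alone has
rotational near-symmetries ("slippage"): several starts can end in
near-equal-error local minima that differ by large rotations.  Points on
the nose break that symmetry, which is why the registration is run from
multiple random initializations and why nose retention in the MRI
matters; see :mod:`noseguard.evaluation` for the cohort-level analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    FIDUCIAL_LABELS,
    HeadPointSet,
    RigidTransform,
    apply_transform,
    build_head_frame,
    fit_rigid_landmarks,
    random_rigid,
)
from .meshes import SurfaceMesh

# defaults for the multi-start ICP; the random-start magnitudes are the
# package's declared perturbation scheme (rotations up to +/-15 deg per
# axis, translations up to +/-10 mm around the initialization)
DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 200
DEFAULT_TOL_MM = 1e-4
INIT_ROTATION_DEG = 15.0
INIT_TRANSLATION_MM = 10.0


@dataclass
class CoregResult:
    """Outcome of a (multi-start) surface registration."""

    transform: RigidTransform
    per_point_residuals: np.ndarray
    rms: float
    n_iterations: int
    init_index: int
    start_rms: np.ndarray = field(default_factory=lambda: np.array([]))
    start_transforms: list[RigidTransform] = field(default_factory=list)
    rms_history: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------
# exact point-to-surface distance
# ---------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point, vectorized.

    ``p`` is (M, 3); ``tri`` is (M, K, 3, 3) candidate triangles per
    query.  Implements the standard barycentric region classification
    (Ericson, Real-Time Collision Detection) with array masks.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = p[:, None, :]
    ab, ac = b - a, c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        # edge parameters, guarded against zero denominators
        t_ab = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        t_bc = np.where(den_bc != 0, (d4 - d3) / np.where(den_bc != 0, den_bc, 1.0), 0.0)
        den_in = va + vb + vc
        den_in = np.where(den_in != 0, den_in, 1.0)
        v_in = vb / den_in
        w_in = vc / den_in

    cand_interior = a + ab * v_in[..., None] + ac * w_in[..., None]
    out = cand_interior
    # apply regions in reverse priority so earlier (vertex) regions win
    m_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(m_bc[..., None], b + (c - b) * t_bc[..., None], out)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_ac[..., None], a + ac * t_ac[..., None], out)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_ab[..., None], a + ab * t_ab[..., None], out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], c, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], b, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], a, out)
    return out


class _MeshProximity:
    """Spatial index for exact nearest-point queries on a triangle mesh.

    Candidate triangles are found through a cKDTree over face centroids
    (plus faces incident to the nearest vertices, which protects against
    centroid pruning misses on stretched triangles); the exact
    point-to-triangle distance is then minimized over candidates.
    """

    def __init__(self, mesh: SurfaceMesh, k_faces: int = 6, k_verts: int = 2):
        if mesh.n_faces == 0:
            raise ValueError("mesh has no faces")
        areas = mesh.triangle_areas()
        if np.any(areas <= 1e-12):
            # drop degenerate faces rather than failing the query
            keep = areas > 1e-12
            self.faces = mesh.faces[keep]
        else:
            self.faces = mesh.faces
        if len(self.faces) == 0:
            raise ValueError("mesh has only degenerate faces")
        self.vertices = mesh.vertices
        self.triangles = self.vertices[self.faces]
        self.centroid_tree = cKDTree(self.triangles.mean(axis=1))
        self.vertex_tree = cKDTree(self.vertices)
        self.k_faces = min(k_faces, len(self.faces))
        self.k_verts = min(k_verts, len(self.vertices))
        # map vertex -> up to max_deg incident faces (padded with 0)
        nv = len(self.vertices)
        counts = np.zeros(nv, dtype=int)
        for col in range(3):
            np.add.at(counts, self.faces[:, col], 1)
        max_deg = int(counts.max())
        incident = np.zeros((nv, max_deg), dtype=np.int64)
        cursor = np.zeros(nv, dtype=int)
        for fi, f in enumerate(self.faces):
            for vid in f:
                incident[vid, cursor[vid]] = fi
                cursor[vid] += 1
        self.incident = incident
        self.incident_valid = cursor

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(np.isfinite(points)):
            raise ValueError("query points must be finite")
        _, fidx = self.centroid_tree.query(points, k=self.k_faces)
        fidx = np.atleast_2d(fidx)
        _, vidx = self.vertex_tree.query(points, k=self.k_verts)
        vidx = np.atleast_2d(vidx)
        extra = self.incident[vidx].reshape(len(points), -1)
        cand = np.concatenate([fidx, extra], axis=1)
        tris = self.triangles[cand]  # (M, K, 3, 3)
        closest = _closest_on_triangles(points, tris)
        d2 = np.sum((closest - points[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return np.sqrt(d2[rows, best]), closest[rows, best]


_PROXIMITY_CACHE: dict[int, tuple[SurfaceMesh, _MeshProximity]] = {}


def _proximity(mesh: SurfaceMesh) -> _MeshProximity:
    key = id(mesh)
    hit = _PROXIMITY_CACHE.get(key)
    if hit is not None and hit[0] is mesh:
        return hit[1]
    prox = _MeshProximity(mesh)
    if len(_PROXIMITY_CACHE) > 32:
        _PROXIMITY_CACHE.clear()
    _PROXIMITY_CACHE[key] = (mesh, prox)
    return prox


def point_to_surface_distance(
    points: np.ndarray, mesh: SurfaceMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Exact unsigned distance from each point to the mesh surface.

    Handles face-interior, edge and vertex closest-point cases exactly;
    returns ``(distances, closest_points)``.
    """
    return _proximity(mesh).query(points)


# ---------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------

def icp_register(
    points: np.ndarray,
    mesh: SurfaceMesh,
    init: RigidTransform | None = None,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL_MM,
    seed: int | np.random.Generator | None = 0,
) -> CoregResult:
    """Multi-start iterative closest point fit of points to a surface.

    Runs ``n_init`` starts: the supplied initialization plus
    ``n_init - 1`` seeded random perturbations of it.  Each start
    alternates exact closest-point correspondence with a least-squares
    rigid fit until the RMS change drops below ``tol`` (mm) or
    ``max_iter`` is reached; the best final RMS wins.  The per-iteration
    RMS of surface distances is non-increasing by construction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise ValueError("ICP needs at least 3 points")
    if not np.all(np.isfinite(points)):
        raise ValueError("ICP points must be finite")
    if init is None:
        init = RigidTransform.identity()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prox = _proximity(mesh)

    starts: list[RigidTransform] = [init]
    center = init.apply(points).mean(axis=0)
    for _ in range(max(0, n_init - 1)):
        perturb = random_rigid(rng, INIT_ROTATION_DEG, INIT_TRANSLATION_MM, center)
        starts.append(perturb @ init)

    # all starts iterate in lockstep so the (dominant) closest-point
    # queries are batched into one spatial lookup per iteration
    n_starts = len(starts)
    n_pts = len(points)
    transforms = list(starts)
    prev_rms = np.full(n_starts, np.inf)
    active = np.ones(n_starts, dtype=bool)
    iter_count = np.zeros(n_starts, dtype=int)
    histories: list[list[float]] = [[] for _ in range(n_starts)]
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        moved = np.concatenate([transforms[s].apply(points) for s in idx])
        d, closest = prox.query(moved)
        d = d.reshape(len(idx), n_pts)
        closest = closest.reshape(len(idx), n_pts, 3)
        rms = np.sqrt(np.mean(d**2, axis=1))
        for row, s in enumerate(idx):
            histories[s].append(float(rms[row]))
            iter_count[s] += 1
            if prev_rms[s] - rms[row] < tol:
                active[s] = False
            else:
                prev_rms[s] = rms[row]
                transforms[s] = fit_rigid_landmarks(points, closest[row])

    moved = np.concatenate([T.apply(points) for T in transforms])
    d_all, _ = prox.query(moved)
    d_all = d_all.reshape(n_starts, n_pts)
    start_rms = np.sqrt(np.mean(d_all**2, axis=1))
    best = int(np.argmin(start_rms))
    return CoregResult(
        transform=transforms[best],
        per_point_residuals=d_all[best],
        rms=float(start_rms[best]),
        n_iterations=int(iter_count[best]),
        init_index=best,
        start_rms=start_rms,
        start_transforms=transforms,
        rms_history=np.array(histories[best]),
    )


# ---------------------------------------------------------------------
# two-step coregistration
# ---------------------------------------------------------------------

def exclude_nose_region(points: HeadPointSet) -> HeadPointSet:
    """Drop head points in the nose region of the MEG head frame.

    Builds the head frame from the set's own fiducials and removes
    points with y > 0 and z < 0 (strict inequalities) in that frame;
    fiducials are never removed.  Works on points in any single frame
    since the head frame is derived from the same set.
    """
    if not points.has_fiducials:
        raise ValueError("nose-region exclusion requires all three fiducials")
    to_head = build_head_frame(
        points.fiducial("nasion"), points.fiducial("lpa"), points.fiducial("rpa")
    )
    head_pts = to_head.apply(points.points)
    in_nose = (head_pts[:, 1] > 0) & (head_pts[:, 2] < 0)
    is_fid = np.isin(points.labels.astype(str), FIDUCIAL_LABELS)
    return points.select(~in_nose | is_fid)


def coregister_two_step(
    headpoints: HeadPointSet,
    fiducials_mri: HeadPointSet | np.ndarray,
    scalp: SurfaceMesh,
    use_nose: bool = True,
    seed: int | np.random.Generator | None = 0,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL_MM,
) -> CoregResult:
    """Two-step device-to-MRI coregistration.

    Step 1 rigidly fits the three digitized fiducials to their marked
    MRI counterparts.  Step 2 refines with multi-start ICP of the
    non-fiducial head points against the scalp surface, starting from
    the step-1 transform.  With ``use_nose=False`` the nose-region
    points (y > 0 and z < 0 in the head frame) are excluded before ICP,
    mirroring how de-faced MRIs must be coregistered.
    """
    if not headpoints.has_fiducials:
        raise ValueError("head points must include nasion, lpa and rpa")
    if isinstance(fiducials_mri, HeadPointSet):
        fids_mri = fiducials_mri.fiducial_array()
    else:
        fids_mri = np.asarray(fiducials_mri, dtype=float)
        if fids_mri.shape != (3, 3):
            raise ValueError("fiducials_mri must be 3 points (nasion, lpa, rpa)")
    fids_meg = headpoints.fiducial_array()
    T_fid = fit_rigid_landmarks(fids_meg, fids_mri)

    pts = headpoints if use_nose else exclude_nose_region(headpoints)
    surface_pts = pts.drop_fiducials()
    if len(surface_pts) == 0:
        d = np.linalg.norm(T_fid.apply(fids_meg) - fids_mri, axis=1)
        return CoregResult(
            transform=T_fid,
            per_point_residuals=d,
            rms=float(np.sqrt(np.mean(d**2))),
            n_iterations=0,
            init_index=0,
            start_rms=np.array([float(np.sqrt(np.mean(d**2)))]),
            start_transforms=[T_fid],
        )
    return icp_register(
        surface_pts.points,
        scalp,
        init=T_fid,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        seed=seed,
    )
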