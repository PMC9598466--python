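"""Exact point-to-surface distance, multi-start ICP, two-step coregistration."""
import numpy as np
import pytest

from noseguard import (
    coregister_two_step,
    fit_rigid_landmarks,
    icp_register,
    make_icosphere,
    point_to_surface_distance,
    random_rigid,
    sample_head_points,
)
from noseguard.geometry import HeadPointSet, RigidTransform
from noseguard.meshes import SurfaceMesh


class TestPointToSurfaceDistance:
    def test_mesh_vertex_has_zero_distance(self):
        mesh = make_icosphere(2, radius=50.0)
        d, closest = point_to_surface_distance(mesh.vertices[::7], mesh)
        assert d.max() < 1e-12
        assert np.allclose(closest, mesh.vertices[::7])

    def test_point_above_triangle_interior(self):
        tri = SurfaceMesh(
            np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]), np.array([[0, 1, 2]])
        )
        d, closest = point_to_surface_distance(np.array([[2.0, 2.0, 5.0]]), tri)
        assert np.isclose(d[0], 5.0, atol=1e-12)
        assert np.allclose(closest[0], [2, 2, 0], atol=1e-12)

    def test_edge_and_vertex_regions(self):
        tri = SurfaceMesh(
            np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]]), np.array([[0, 1, 2]])
        )
        # beyond the corner at the origin
        d, closest = point_to_surface_distance(np.array([[-3.0, -4.0, 0.0]]), tri)
        assert np.isclose(d[0], 5.0) and np.allclose(closest[0], 0)
        # perpendicular to the x-axis edge
        d, closest = point_to_surface_distance(np.array([[5.0, -2.0, 0.0]]), tri)
        assert np.isclose(d[0], 2.0) and np.allclose(closest[0], [5, 0, 0])

    def test_unit_icosphere_external_point(self):
        mesh = make_icosphere(4)
        d, _ = point_to_surface_distance(np.array([[2.0, 0.0, 0.0]]), mesh)
        # max chord sagitta of a level-4 icosphere facet bounds the error
        tri = mesh.vertices[mesh.faces]
        sagitta = 1.0 - np.linalg.norm(tri.mean(axis=1), axis=1).min()
        assert d[0] == pytest.approx(1.0, abs=sagitta + 1e-12)

    def test_empty_mesh_rejected(self):
        empty = SurfaceMesh(np.zeros((3, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            point_to_surface_distance(np.zeros((1, 3)), empty)


class TestIcpRegister:
    def test_points_on_mesh_identity_init(self, rng):
        mesh = make_icosphere(4, radius=80.0)
        pts = mesh.vertices[rng.choice(len(mesh.vertices), 60, replace=False)]
        res = icp_register(pts, mesh, n_init=1, seed=0)
        assert res.rms < 1e-9
        rot, tr = res.transform.error_to(RigidTransform.identity())
        assert rot < 1e-6 and tr < 1e-6

    def test_construct_and_recover(self, noiseless_phantom, rng):
        pts = sample_head_points(noiseless_phantom, 80, 10, seed=11)
        truth = RigidTransform.identity()
        perturb = random_rigid(rng, 8, 6, center=pts.points.mean(axis=0))
        res = icp_register(
            pts.drop_fiducials().points,
            noiseless_phantom.true_scalp,
            init=perturb,
            n_init=10,
            tol=1e-4,
            seed=1,
        )
        rot, tr = res.transform.error_to(truth)
        assert rot < 0.5 and tr < 1.0

    def test_best_of_ten_no_worse_than_single_start(self, noiseless_phantom, rng):
        pts = sample_head_points(noiseless_phantom, 60, 8, seed=12)
        init = random_rigid(rng, 10, 8, center=pts.points.mean(axis=0))
        multi = icp_register(
            pts.drop_fiducials().points, noiseless_phantom.true_scalp,
            init=init, n_init=10, seed=2,
        )
        single = icp_register(
            pts.drop_fiducials().points, noiseless_phantom.true_scalp,
            init=init, n_init=1, seed=2,
        )
        assert multi.rms <= single.rms + 1e-12
        assert multi.start_rms[multi.init_index] <= multi.start_rms.min() + 1e-12

    def test_rms_history_non_increasing(self, noiseless_phantom, rng):
        pts = sample_head_points(noiseless_phantom, 60, 8, seed=13)
        init = random_rigid(rng, 10, 8, center=pts.points.mean(axis=0))
        res = icp_register(
            pts.drop_fiducials().points, noiseless_phantom.true_scalp,
            init=init, n_init=3, seed=3,
        )
        h = res.rms_history
        assert np.all(np.diff(h) <= 1e-9)
        assert np.isclose(
            res.rms, np.sqrt(np.mean(res.per_point_residuals**2)), atol=1e-9
        )

    def test_invalid_inputs_rejected(self):
        mesh = make_icosphere(2, radius=50.0)
        with pytest.raises(ValueError):
            icp_register(np.zeros((2, 3)), mesh)
        bad = np.full((5, 3), np.nan)
        with pytest.raises(ValueError):
            icp_register(bad, mesh)


def _meg_set(points, labels, frame="device"):
    return HeadPointSet(np.asarray(points, float), np.asarray(labels, object), frame)


class TestCoregisterTwoStep:
    def test_reduces_to_fiducial_fit_without_head_points(self, rng):
        fids_mri = np.array([[0.0, 95, 10], [-70, 0, 0], [72, 0, 0]])
        T = random_rigid(rng, 20, 30)
        meg = _meg_set(T.apply(fids_mri), ["nasion", "lpa", "rpa"])
        scalp = make_icosphere(3, radius=90.0)
        res = coregister_two_step(meg, fids_mri, scalp, seed=0)
        expected = fit_rigid_landmarks(meg.points, fids_mri)
        assert np.allclose(res.transform.matrix, expected.matrix, atol=1e-9)
        assert res.n_iterations == 0

    def test_noiseless_phantom_recovers_ground_truth(self, noiseless_phantom):
        pts = sample_head_points(noiseless_phantom, 80, 10, noise_sd_mm=0.0, seed=21)
        res = coregister_two_step(
            pts, noiseless_phantom.fiducials_mri.fiducial_array(),
            noiseless_phantom.true_scalp, seed=5,
        )
        rot, tr = res.transform.error_to(RigidTransform.identity())
        assert tr < 0.5 and rot < 0.5

    def test_head_points_compensate_fiducial_error(self, noiseless_phantom, rng):
        """Perturbed fiducials, clean surface points: ICP beats step 1."""
        pts = sample_head_points(noiseless_phantom, 100, 10, noise_sd_mm=0.0, seed=22)
        fids_true = noiseless_phantom.fiducials_mri.fiducial_array()
        fids_marked = fids_true + rng.normal(0, 5.0, (3, 3))
        step1 = fit_rigid_landmarks(pts.fiducial_array(), fids_marked)
        res = coregister_two_step(
            pts, fids_marked, noiseless_phantom.true_scalp, seed=6
        )
        identity = RigidTransform.identity()
        rot1, tr1 = step1.error_to(identity)
        rot2, tr2 = res.transform.error_to(identity)
        assert tr2 < tr1 and rot2 < rot1

    def test_missing_fiducial_rejected(self):
        meg = _meg_set([[0, 90, 0], [-70, 0, 0], [0, 0, 80]], ["nasion", "lpa", "scalp"])
        with pytest.raises(ValueError):
            coregister_two_step(meg, np.zeros((3, 3)), make_icosphere(2, 90.0))
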