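"""Rigid transforms, head-frame construction and landmark fitting."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from noseguard import (
    DegenerateGeometryError,
    FrameError,
    HeadPointSet,
    RigidTransform,
    apply_transform,
    build_head_frame,
    fit_rigid_landmarks,
    random_rigid,
)

CANONICAL = {
    "nasion": np.array([0.0, 100.0, 0.0]),
    "lpa": np.array([-75.0, 0.0, 0.0]),
    "rpa": np.array([75.0, 0.0, 0.0]),
}


class TestRigidTransform:
    def test_rotation_block_validated(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError):
            RigidTransform(bad)
        mirror = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(mirror)

    def test_inverse_roundtrip(self, rng):
        T = random_rigid(rng, 40, 60)
        p = rng.normal(size=(20, 3)) * 50
        assert np.allclose(T.inverse().apply(T.apply(p)), p, atol=1e-9)
        assert np.allclose((T.inverse() @ T).matrix, np.eye(4), atol=1e-9)

    def test_composition_associates_with_application(self, rng):
        T1 = random_rigid(rng, 30, 40)
        T2 = random_rigid(rng, 30, 40)
        p = rng.normal(size=(15, 3)) * 30
        assert np.allclose((T2 @ T1).apply(p), T2.apply(T1.apply(p)), atol=1e-12)

    def test_identity_leaves_points(self, rng):
        p = rng.normal(size=(8, 3))
        assert np.array_equal(RigidTransform.identity().apply(p), p)

    def test_json_tsv_roundtrip(self, rng, tmp_path):
        T = random_rigid(rng, 25, 35)
        T2 = RigidTransform.from_json(T.to_json())
        assert np.allclose(T.matrix, T2.matrix, atol=1e-12)
        T.to_tsv(tmp_path / "t.tsv")
        T3 = RigidTransform.from_tsv(tmp_path / "t.tsv")
        assert np.allclose(T.matrix, T3.matrix, atol=1e-9)


class TestBuildHeadFrame:
    def test_canonical_configuration_gives_identity(self):
        T = build_head_frame(**CANONICAL)
        assert np.allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_transformed_fiducials_satisfy_frame_axioms(self, rng):
        for _ in range(10):
            M = random_rigid(rng, 60, 80)
            nas, lpa, rpa = (M.apply(CANONICAL[k]) for k in ("nasion", "lpa", "rpa"))
            T = build_head_frame(nas, lpa, rpa)
            nas_h, lpa_h, rpa_h = T.apply(nas), T.apply(lpa), T.apply(rpa)
            # nasion on +y axis; LPA/RPA on the x axis
            assert abs(nas_h[0]) < 1e-9 and abs(nas_h[2]) < 1e-9 and nas_h[1] > 0
            assert abs(lpa_h[1]) < 1e-9 and abs(lpa_h[2]) < 1e-9
            assert abs(rpa_h[1]) < 1e-9 and abs(rpa_h[2]) < 1e-9
            assert lpa_h[0] < 0 < rpa_h[0]

    def test_rotated_points_map_back_to_canonical(self, rng):
        M = random_rigid(rng, 45, 50)
        moved = {k: M.apply(v) for k, v in CANONICAL.items()}
        T = build_head_frame(moved["nasion"], moved["lpa"], moved["rpa"])
        for k in CANONICAL:
            assert np.allclose(T.apply(moved[k]), CANONICAL[k], atol=1e-9)

    def test_degenerate_fiducials_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            build_head_frame(CANONICAL["nasion"], CANONICAL["lpa"], CANONICAL["lpa"])
        with pytest.raises(DegenerateGeometryError):
            build_head_frame(np.zeros(3), CANONICAL["lpa"], CANONICAL["rpa"])


class TestFitRigidLandmarks:
    def test_identity_when_src_equals_dst(self, rng):
        src = rng.normal(size=(6, 3)) * 40
        T = fit_rigid_landmarks(src, src)
        assert np.allclose(T.matrix, np.eye(4), atol=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_recovers_random_rigid_exactly(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(5, 3)) * 60
        truth = random_rigid(rng, 90, 100)
        T = fit_rigid_landmarks(src, truth.apply(src))
        rot_err, tr_err = T.error_to(truth)
        assert rot_err < 1e-9 and tr_err < 1e-9

    def test_mirrored_target_never_returns_reflection(self, rng):
        src = rng.normal(size=(10, 3)) * 50
        dst = src * np.array([-1.0, 1.0, 1.0])
        T = fit_rigid_landmarks(src, dst)
        assert np.isclose(np.linalg.det(T.rotation), 1.0, atol=1e-9)
        assert np.linalg.norm(T.apply(src) - dst) > 1.0  # residual unavoidable

    def test_pair_order_invariance(self, rng):
        src = rng.normal(size=(8, 3)) * 30
        truth = random_rigid(rng, 50, 40)
        dst = truth.apply(src) + rng.normal(0, 0.5, (8, 3))
        perm = rng.permutation(8)
        T1 = fit_rigid_landmarks(src, dst)
        T2 = fit_rigid_landmarks(src[perm], dst[perm])
        assert np.allclose(T1.matrix, T2.matrix, atol=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_landmarks(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_rigid_landmarks(line, line + 1.0)


class TestHeadPointSet:
    def _pts(self, frame="device"):
        pts = np.array([[0, 100, 0], [-75, 0, 0], [75, 0, 0], [0, 0, 90.0]])
        labels = np.array(["nasion", "lpa", "rpa", "scalp"], dtype=object)
        return HeadPointSet(pts, labels, frame=frame)

    def test_fiducial_access_and_uniqueness(self):
        ps = self._pts()
        assert np.array_equal(ps.fiducial("nasion"), [0, 100, 0])
        with pytest.raises(ValueError):
            HeadPointSet(np.zeros((2, 3)), np.array(["nasion", "nasion"]))

    def test_apply_transform_updates_frame_and_keeps_labels(self, rng):
        ps = self._pts()
        T = random_rigid(rng, 20, 10)
        T = RigidTransform(T.matrix, from_frame="device", to_frame="head")
        out = apply_transform(T, ps)
        assert out.frame == "head"
        assert np.array_equal(out.labels, ps.labels)
        with pytest.raises(FrameError):
            apply_transform(T, self._pts(frame="mri_world"))

    def test_tsv_roundtrip(self, tmp_path):
        ps = self._pts()
        ps.to_tsv(tmp_path / "p.tsv")
        back = HeadPointSet.from_tsv(tmp_path / "p.tsv", frame="device")
        assert np.allclose(back.points, ps.points)
        assert list(back.labels) == list(ps.labels)
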