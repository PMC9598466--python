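"""Canonical icosphere, scalp extraction, mesh warping and comparison."""
import numpy as np
import pytest

from noseguard import (
    DeformationField,
    Volume,
    compare_surfaces,
    extract_scalp,
    make_icosphere,
    random_rigid,
    warp_canonical_innerskull,
)
from noseguard.meshes import SurfaceMesh


class TestIcosphere:
    @pytest.mark.parametrize("level", range(6))
    def test_vertex_count_formula(self, level):
        mesh = make_icosphere(level)
        assert mesh.n_vertices == 10 * 4**level + 2
        assert mesh.euler_characteristic() == 2

    def test_level0_is_icosahedron(self):
        mesh = make_icosphere(0)
        assert mesh.n_vertices == 12 and mesh.n_faces == 20

    def test_vertices_on_unit_sphere(self):
        mesh = make_icosphere(3)
        assert np.allclose(np.linalg.norm(mesh.vertices, axis=1), 1.0, atol=1e-9)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            make_icosphere(-1)


def _ellipsoid_volume(semi=(40.0, 50.0, 45.0), voxel=2.0, shape=(64, 70, 66)):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = -voxel * (np.array(shape) - 1) / 2
    vol = Volume(np.zeros(shape), affine)
    pts = vol.grid_world()
    mask = (((pts / np.array(semi)) ** 2).sum(axis=-1)) <= 1.0
    return Volume(mask.astype(float), affine), np.array(semi)


class TestExtractScalp:
    def test_ellipsoid_surface_within_one_voxel(self):
        vol, semi = _ellipsoid_volume()
        mesh = extract_scalp(vol, 0.5)
        # implicit ellipsoid value ~1 on the surface; convert to distance
        # via the local gradient of the implicit function
        v = mesh.vertices
        val = ((v / semi) ** 2).sum(axis=1)
        grad = 2 * v / semi**2
        dist = np.abs(val - 1.0) / np.linalg.norm(grad, axis=1)
        assert dist.max() < 2.0  # one 2-mm voxel

    def test_output_closed_surface(self):
        vol, _ = _ellipsoid_volume()
        mesh = extract_scalp(vol, 0.5)
        assert mesh.euler_characteristic() == 2

    def test_noise_blob_outside_head_is_dropped(self):
        vol, _ = _ellipsoid_volume()
        data = vol.data.copy()
        data[2:5, 2:5, 2:5] = 1.0  # isolated island far from the head
        mesh_clean = extract_scalp(vol, 0.5)
        mesh_noisy = extract_scalp(Volume(data, vol.affine), 0.5)
        corner = vol.voxel_to_world(np.array([[3.0, 3.0, 3.0]]))[0]
        d = np.linalg.norm(mesh_noisy.vertices - corner, axis=1)
        assert d.min() > 10.0
        assert mesh_noisy.n_vertices == mesh_clean.n_vertices

    def test_empty_mask_rejected(self):
        vol, _ = _ellipsoid_volume()
        with pytest.raises(ValueError):
            extract_scalp(vol, 2.0)


class TestWarpCanonicalInnerskull:
    def test_identity_field_leaves_mesh(self, template):
        fld = DeformationField.identity(
            template.template_volume.shape, template.affine
        )
        mesh = warp_canonical_innerskull(template.canonical_inner_skull, fld)
        assert np.allclose(mesh.vertices, template.canonical_inner_skull.vertices)

    def test_topology_preserved(self, template, phantom):
        mesh = warp_canonical_innerskull(
            template.canonical_inner_skull, phantom.true_deformation
        )
        assert mesh.n_vertices == 2562 and mesh.n_faces == 5120
        assert np.array_equal(mesh.faces, template.canonical_inner_skull.faces)

    def test_vertex_outside_grid_rejected(self, template):
        fld = DeformationField.identity(
            template.template_volume.shape, template.affine
        )
        far = SurfaceMesh(
            template.canonical_inner_skull.vertices + 500.0,
            template.canonical_inner_skull.faces,
        )
        with pytest.raises(ValueError):
            warp_canonical_innerskull(far, fld)


class TestCompareSurfaces:
    def test_identical_meshes_zero(self):
        m = make_icosphere(2, radius=60.0)
        cmp = compare_surfaces(m, m)
        assert cmp.mean_mm == 0.0

    def test_pure_translation_removed_by_alignment(self):
        m = make_icosphere(3, radius=60.0)
        shifted = SurfaceMesh(m.vertices + np.array([3.0, 0.0, 0.0]), m.faces)
        raw = compare_surfaces(m, shifted, align=False)
        assert np.isclose(raw.mean_mm, 3.0, atol=1e-9)
        aligned = compare_surfaces(m, shifted, align=True)
        assert aligned.mean_mm < 1e-6

    def test_alignment_never_increases_mean(self, rng):
        m = make_icosphere(2, radius=50.0)
        for _ in range(5):
            noisy = SurfaceMesh(
                random_rigid(rng, 10, 5).apply(m.vertices)
                + rng.normal(0, 1.0, m.vertices.shape),
                m.faces,
            )
            raw = compare_surfaces(m, noisy, align=False)
            aligned = compare_surfaces(m, noisy, align=True)
            assert aligned.mean_mm <= raw.mean_mm + 1e-9
            assert np.isclose(
                aligned.mean_mm, aligned.per_vertex_distance.mean(), atol=1e-9
            )

    def test_symmetric_when_unaligned(self, rng):
        m = make_icosphere(2, radius=50.0)
        other = SurfaceMesh(m.vertices + rng.normal(0, 2, m.vertices.shape), m.faces)
        ab = compare_surfaces(m, other, align=False)
        ba = compare_surfaces(other, m, align=False)
        assert np.allclose(ab.per_vertex_distance, ba.per_vertex_distance)

    def test_topology_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_surfaces(make_icosphere(2), make_icosphere(3))
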