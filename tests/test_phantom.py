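"""Synthetic template and phantom-subject generation."""
import numpy as np
import pytest
from dataclasses import replace

from noseguard import (
    RigidTransform,
    bool_volume,
    make_head_phantom,
    make_template,
    point_to_surface_distance,
    random_rigid,
    sample_head_points,
)
from noseguard.phantom import TPM_CLASSES


class TestMakeTemplate:
    def test_deterministic_given_seed(self):
        a = make_template(seed=5)
        b = make_template(seed=5)
        assert np.array_equal(a.template_volume.data, b.template_volume.data)
        for name in TPM_CLASSES:
            assert np.array_equal(a.tpm[name].data, b.tpm[name].data)
        assert np.array_equal(
            a.canonical_inner_skull.vertices, b.canonical_inner_skull.vertices
        )

    def test_tpm_classes_sum_to_one(self, template):
        total = sum(template.tpm[name].data for name in TPM_CLASSES)
        assert np.allclose(total, 1.0, atol=1e-6)

    def test_face_class_zero_on_nose(self, template):
        nose = template.masks["nose"].data
        assert nose.any()
        assert np.all(template.tpm["face"].data[nose] == 0.0)

    def test_inner_skull_inside_cranium(self, template):
        inside = (
            template.masks["brain"].astype(float).sample(
                template.canonical_inner_skull.vertices
            )
            + template.masks["skull"].astype(float).sample(
                template.canonical_inner_skull.vertices
            )
        )
        assert template.canonical_inner_skull.n_vertices == 2562
        assert np.all(inside > 0.5)

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_template(grid_shape=(48, 48, 48), voxel_size_mm=1.0)
        with pytest.raises(ValueError):
            make_template(grid_shape=(32, 56, 48))
        with pytest.raises(ValueError):
            make_template(voxel_size_mm=-1.0)


class TestMakeHeadPhantom:
    def test_zero_deformation_reproduces_template(self, template):
        subj = make_head_phantom(
            template, deform_amplitude_mm=0.0, seed=0, intensity_noise_sd=0.0
        )
        assert np.allclose(subj.volume.data, template.template_volume.data, atol=1e-9)

    def test_deterministic_given_seed(self, template):
        a = make_head_phantom(template, 4.0, seed=3)
        b = make_head_phantom(template, 4.0, seed=3)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(
            a.true_deformation.displacement, b.true_deformation.displacement
        )

    def test_deformation_field_invertible(self, phantom):
        fld = phantom.true_deformation
        assert fld.jacobian_determinant().min() > 0
        assert fld.inverse_consistency_residual() < 0.1

    def test_masks_consistent(self, phantom):
        assert not np.any(phantom.brain_mask.data & phantom.face_mask.data)
        assert not np.any(phantom.nose_mask.data & phantom.face_mask.data)
        assert np.all(phantom.head_mask.data[phantom.nose_mask.data])

    def test_fiducials_near_head_boundary(self, phantom):
        from scipy.ndimage import distance_transform_edt

        head = phantom.head_mask.data
        voxel = phantom.head_mask.voxel_size.mean()
        d_out = distance_transform_edt(~head) * voxel
        d_in = distance_transform_edt(head) * voxel
        boundary_dist = np.maximum(d_out, d_in)  # one of the two is 0 at the surface
        for pt in phantom.fiducials_mri.points:
            vox = phantom.head_mask.world_to_voxel(pt)[0].round().astype(int)
            assert boundary_dist[tuple(vox)] <= 1.5 * voxel


class TestSampleHeadPoints:
    def test_noiseless_points_lie_on_scalp(self, noiseless_phantom):
        pts = sample_head_points(noiseless_phantom, 50, 5, noise_sd_mm=0.0, seed=2)
        d, _ = point_to_surface_distance(
            pts.drop_fiducials().points, noiseless_phantom.true_scalp
        )
        assert d.max() < 1e-6

    def test_default_scalp_count_is_100(self, phantom):
        pts = sample_head_points(phantom, seed=0)
        assert int(np.sum(pts.labels == "scalp")) == 100

    def test_device_transform_inverse_returns_to_surface(self, noiseless_phantom, rng):
        dev = random_rigid(rng, 25, 40)
        noise = 1.0
        pts = sample_head_points(
            noiseless_phantom, 40, 6, noise_sd_mm=noise, device_transform=dev, seed=4
        )
        back = dev.inverse().apply(pts.drop_fiducials().points)
        d, _ = point_to_surface_distance(back, noiseless_phantom.true_scalp)
        assert d.max() < 5 * noise  # within gaussian noise bounds

    def test_nose_labels_in_nose_region(self, phantom):
        pts = sample_head_points(phantom, 20, 8, seed=5)
        lo, hi = phantom.nose_bbox_world()
        nose_pts = pts.by_label(["nose"]).points
        assert len(nose_pts) == 8
        assert np.all((nose_pts >= lo - 1e-9) & (nose_pts <= hi + 1e-9))

    def test_defaced_phantom_has_no_nose_to_sample(self, phantom, template):
        defaced = replace(
            phantom,
            nose_mask=bool_volume(
                np.zeros(phantom.nose_mask.shape, dtype=bool), phantom.nose_mask.affine
            ),
        )
        with pytest.raises(ValueError):
            sample_head_points(defaced, 20, 5, seed=0)

    def test_too_few_points_rejected(self, phantom):
        with pytest.raises(ValueError):
            sample_head_points(phantom, 1, 1, seed=0)
        with pytest.raises(ValueError):
            sample_head_points(phantom, 10, 0, noise_sd_mm=-1.0, seed=0)
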