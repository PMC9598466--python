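"""Two-step MEG-MRI coregistration on a phantom with known truth.

Digitized head points (noisy fiducials + ~100 scalp points + nose
points) are mapped into a random device frame; the two-step procedure
(rigid fiducial fit, then multi-start ICP against the scalp surface)
must recover the inverse of that device transform.
"""
import numpy as np

from noseguard import (
    coregister_two_step,
    fiducial_registration_error,
    make_head_phantom,
    make_template,
    random_rigid,
    sample_head_points,
)

template = make_template(seed=0)
subject = make_head_phantom(template, deform_amplitude_mm=4.0, seed=1)

rng = np.random.default_rng(5)
device_T = random_rigid(rng, max_rotation_deg=20, max_translation_mm=30)  # mri->device
points = sample_head_points(
    subject, n_scalp=100, n_nose=10, noise_sd_mm=1.5,
    fiducial_noise_sd_mm=2.9, device_transform=device_T, seed=3,
)
fids_marked = subject.fiducials_mri.fiducial_array() + rng.normal(0, 2.9, (3, 3))

result = coregister_two_step(points, fids_marked, subject.true_scalp, seed=7)
rot_err, tr_err = result.transform.error_to(device_T.inverse())
fre = fiducial_registration_error(result.transform, points.fiducial_array(), fids_marked)

print(f"ICP converged in {result.n_iterations} iterations "
      f"(winning start {result.init_index} of 10)")
print(f"residual RMS to scalp surface: {result.rms:.2f} mm "
      f"(dominated by the 1.5 mm digitization noise)")
print(f"fiducial registration error:   {fre:.2f} mm "
      f"(the proxy reported with real data; inflated by marking noise)")
print(f"true transform error:          {rot_err:.2f} deg rotation, "
      f"{tr_err:.2f} mm translation (known only in simulation)")
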