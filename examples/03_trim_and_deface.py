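"""Nose-preserving trimming versus standard de-facing.

The subject is nonlinearly registered to the template, the tissue
probability map (with its face-without-nose class) is warped into
subject space, and voxels whose face probability exceeds 10% are
removed.  The comparator removes the full face-covering cuboid, nose
included.
"""
import numpy as np

from noseguard import (
    bool_volume,
    deface_full,
    label_tissues,
    make_head_phantom,
    make_template,
    nonlinear_register,
    trim_face,
)

template = make_template(seed=0)
subject = make_head_phantom(template, deform_amplitude_mm=4.0, seed=1)

fld = nonlinear_register(subject.volume, template.template_volume)
probs = label_tissues(subject.volume, template, fld)

trimmed, trim_report = trim_face(
    subject.volume, probs["face"], threshold=0.10,
    brain_mask=subject.brain_mask, nose_mask=subject.nose_mask,
    head_mask=subject.head_mask,
)
print("trimming report:")
print(trim_report.to_json())

grid = subject.volume.grid_world().reshape(-1, 3)
deface_mask = (
    template.masks["deface"].astype(float)
    .sample(grid + fld.sample_inverse(grid)).reshape(subject.volume.shape) > 0.35
)
defaced, deface_report = deface_full(
    subject.volume, bool_volume(deface_mask, subject.volume.affine),
    brain_mask=subject.brain_mask, nose_mask=subject.nose_mask,
)
print("\nde-facing report:")
print(deface_report.to_json())

nose = subject.nose_mask.data
print(f"\nnose voxels surviving trimming:  {int(np.count_nonzero(trimmed.data[nose]))}"
      f" of {int(nose.sum())} (all kept)")
print(f"nose voxels surviving de-facing: {int(np.count_nonzero(defaced.data[nose]))}"
      f" (all removed)")
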