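"""Coregistration error metrics and the nose-point exclusion rule.

The fiducial registration error — the mean Euclidean distance between
the transformed MEG fiducials and their MRI-marked counterparts — is
the field's standard proxy for coregistration quality; since marked
fiducials are themselves noisy, the cohort simulation also reports the
error against the known ground-truth device transform (see
:mod:`noseguard.cohort`).
"""
from __future__ import annotations

import numpy as np

from .geometry import FIDUCIAL_LABELS, HeadPointSet, RigidTransform
from .stats import StatResult, jzs_bf01, welch_t, wilcoxon_signed_rank  # noqa: F401

__all__ = [
    "fiducial_registration_error",
    "exclude_nose_points",
    "StatResult",
    "wilcoxon_signed_rank",
    "welch_t",
    "jzs_bf01",
]


def _as_fiducial_array(fids) -> np.ndarray:
    if isinstance(fids, HeadPointSet):
        return fids.fiducial_array()
    arr = np.asarray(fids, dtype=float)
    if arr.shape != (3, 3):
        raise ValueError("expected 3 fiducials (nasion, lpa, rpa) as a 3x3 array")
    return arr


def fiducial_registration_error(
    T: RigidTransform, fids_meg, fids_mri
) -> float:
    """Mean Euclidean distance between transformed MEG and MRI fiducials.

    ``T`` maps device coordinates to MRI world coordinates; the three
    fiducials on each side must be ordered/labeled nasion, LPA, RPA.
    """
    meg = _as_fiducial_array(fids_meg)
    mri = _as_fiducial_array(fids_mri)
    d = np.linalg.norm(T.apply(meg) - mri, axis=1)
    return float(d.mean())


def exclude_nose_points(pts: HeadPointSet) -> HeadPointSet:
    """Remove digitized points with y > 0 and z < 0 in the head frame.

    This is the published rule for stripping nose/face points before
    coregistering against a de-faced MRI: anterior (y > 0) points below
    the fiducial plane (z < 0) are dropped.  Both inequalities are
    strict, so boundary points are kept, and fiducials are never
    removed.  The rule is frame-dependent and only defined in the
    ``head`` frame.
    """
    if pts.frame != "head":
        raise ValueError(
            f"nose-point exclusion is defined in the 'head' frame, got {pts.frame!r}"
        )
    in_nose = (pts.points[:, 1] > 0) & (pts.points[:, 2] < 0)
    is_fid = np.isin(pts.labels.astype(str), FIDUCIAL_LABELS)
    return pts.select(~in_nose | is_fid)
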