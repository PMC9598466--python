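"""Anonymization operators: nose-preserving face trimming and full de-facing.

``trim_face`` removes only the voxels the atlas labels as face tissue
(face probability strictly above 10% by default), leaving the nose in
place; ``deface_full`` is the comparator that removes the whole face
including the nose.  Removed voxels are set to 0 (air), which keeps the
operation deterministic; everything else is bit-identical to the input.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .volume import Volume

DEFAULT_FACE_THRESHOLD = 0.10


@dataclass
class AnonymizationReport:
    """Audit trail for an anonymization operation."""

    method: str
    n_voxels_removed: int
    n_voxels_changed: int
    removed_fraction_of_head: float
    brain_voxels_altered: int | None = None
    nose_voxels_altered: int | None = None
    threshold: float | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _count_altered(before: np.ndarray, after: np.ndarray, mask: Volume | None):
    if mask is None:
        return None
    return int(np.sum((before != after) & np.asarray(mask.data, dtype=bool)))


def _head_fraction(removal: np.ndarray, before: np.ndarray, head_mask: Volume | None):
    if head_mask is not None:
        head = np.asarray(head_mask.data, dtype=bool)
    else:
        head = before != 0
    n_head = int(head.sum())
    if n_head == 0:
        return 0.0
    return float(np.sum(removal & head)) / n_head


def trim_face(
    volume: Volume,
    face_prob: Volume,
    threshold: float = DEFAULT_FACE_THRESHOLD,
    brain_mask: Volume | None = None,
    nose_mask: Volume | None = None,
    head_mask: Volume | None = None,
) -> tuple[Volume, AnonymizationReport]:
    """Remove voxels whose face-class probability exceeds ``threshold``.

    The comparison is strict (a voxel at exactly the threshold is
    retained).  Optional masks enrich the report with safety counts;
    they do not influence the removal.
    """
    if not volume.same_grid(face_prob):
        raise ValueError("face probability map is not on the volume's grid")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    prob = np.asarray(face_prob.data, dtype=float)
    if prob.min() < -1e-6 or prob.max() > 1.0 + 1e-6:
        raise ValueError("face probabilities must lie in [0, 1]")
    removal = prob > threshold
    out = np.array(volume.data, copy=True)
    out[removal] = 0
    report = AnonymizationReport(
        method="trim",
        n_voxels_removed=int(removal.sum()),
        n_voxels_changed=int(np.sum(out != volume.data)),
        removed_fraction_of_head=_head_fraction(removal, volume.data, head_mask),
        brain_voxels_altered=_count_altered(volume.data, out, brain_mask),
        nose_voxels_altered=_count_altered(volume.data, out, nose_mask),
        threshold=threshold,
    )
    return Volume(out, volume.affine.copy()), report


def deface_full(
    volume: Volume,
    face_mask_with_nose: Volume,
    brain_mask: Volume | None = None,
    nose_mask: Volume | None = None,
    head_mask: Volume | None = None,
) -> tuple[Volume, AnonymizationReport]:
    """Zero out every voxel of the full face mask (nose included).

    Comparator semantics for the standard de-facing condition: the mask
    is applied verbatim, so the nose is removed along with the face.
    """
    if not volume.same_grid(face_mask_with_nose):
        raise ValueError("face mask is not on the volume's grid")
    removal = np.asarray(face_mask_with_nose.data, dtype=bool)
    out = np.array(volume.data, copy=True)
    out[removal] = 0
    report = AnonymizationReport(
        method="deface",
        n_voxels_removed=int(removal.sum()),
        n_voxels_changed=int(np.sum(out != volume.data)),
        removed_fraction_of_head=_head_fraction(removal, volume.data, head_mask),
        brain_voxels_altered=_count_altered(volume.data, out, brain_mask),
        nose_voxels_altered=_count_altered(volume.data, out, nose_mask),
    )
    return Volume(out, volume.affine.copy()), report
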