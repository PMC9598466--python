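"""Rigid transforms, labeled head point sets, and landmark alignment.

Coordinate frames
-----------------
Three frames appear throughout the package, all right-handed and in mm:

``device``
    The digitizer/MEG device frame in which head points are recorded.
``head``
    The Neuromag-style head frame derived from the three anatomical
    fiducials: x-axis from LPA toward RPA, origin at the foot of the
    perpendicular from the nasion to the LPA-RPA line, y-axis toward
    the nasion, z-axis = x cross y (up).
``mri_world``
    World coordinates of the structural MRI (NIfTI affine applied).

The nose-point exclusion rule ("y > 0 and z < 0") is defined in the
``head`` frame only; see :func:`noseguard.evaluation.exclude_nose_points`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

FIDUCIAL_LABELS = ("nasion", "lpa", "rpa")


class FrameError(ValueError):
    """Raised when a transform is applied across incompatible frames."""


class DegenerateGeometryError(ValueError):
    """Raised for collinear/coincident landmark configurations."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body map (rotation + translation) between frames.

    Stored as a 4x4 homogeneous matrix.  ``from_frame``/``to_frame`` are
    optional tags; when both a transform and a point set carry tags they
    are checked on application.
    """

    matrix: np.ndarray
    from_frame: str | None = None
    to_frame: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform matrix must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block is a reflection (det < 0)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row must be [0, 0, 0, 1]")
        object.__setattr__(self, "matrix", m)

    # -- constructors --------------------------------------------------
    @classmethod
    def identity(cls, frame: str | None = None) -> "RigidTransform":
        return cls(np.eye(4), from_frame=frame, to_frame=frame)

    @classmethod
    def from_rotation_translation(
        cls,
        R: np.ndarray,
        t: np.ndarray,
        from_frame: str | None = None,
        to_frame: str | None = None,
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=float)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m, from_frame=from_frame, to_frame=to_frame)

    # -- accessors -----------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation as a single angle in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    # -- algebra -------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self after other``: (self @ other)(p) = self(other(p))."""
        if (
            self.from_frame is not None
            and other.to_frame is not None
            and self.from_frame != other.to_frame
        ):
            raise FrameError(
                f"cannot compose: {other.to_frame!r} -> {self.from_frame!r}"
            )
        return RigidTransform(
            self.matrix @ other.matrix,
            from_frame=other.from_frame,
            to_frame=self.to_frame,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        t = -R @ self.translation
        return RigidTransform.from_rotation_translation(
            R, t, from_frame=self.to_frame, to_frame=self.from_frame
        )

    # -- error metrics -------------------------------------------------
    def error_to(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation deg, translation mm) discrepancy between transforms."""
        delta = self.compose(other.inverse())
        return delta.rotation_angle_deg(), float(np.linalg.norm(delta.translation))

    # -- serialization -------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "matrix": self.matrix.tolist(),
            "from_frame": self.from_frame,
            "to_frame": self.to_frame,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RigidTransform":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            np.asarray(payload["matrix"], dtype=float),
            from_frame=payload.get("from_frame"),
            to_frame=payload.get("to_frame"),
        )

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t", fmt="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "RigidTransform":
        return cls(np.loadtxt(path, delimiter="\t"))


def random_rigid(
    rng: np.random.Generator,
    max_rotation_deg: float,
    max_translation_mm: float,
    center: np.ndarray | None = None,
) -> RigidTransform:
    """Uniform per-axis random rotation and translation, about ``center``."""
    angles = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    if center is not None:
        center = np.asarray(center, dtype=float)
        t = t + center - R @ center
    return RigidTransform.from_rotation_translation(R, t)


@dataclass
class HeadPointSet:
    """Labeled 3D points (fiducials, scalp and nose points) in one frame.

    ``source_points``, when present, holds the noiseless mri_world
    locations each emitted point was sampled from (simulation metadata
    used for ground-truth error evaluation; row-aligned with ``points``).
    """

    points: np.ndarray
    labels: np.ndarray
    frame: str | None = None
    source_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.points.shape[1] != 3:
            raise ValueError("points must be N x 3")
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        for lab in FIDUCIAL_LABELS:
            if np.sum(self.labels == lab) > 1:
                raise ValueError(f"duplicate fiducial label {lab!r}")

    def __len__(self) -> int:
        return len(self.points)

    # -- selection -----------------------------------------------------
    def fiducial(self, label: str) -> np.ndarray:
        if label not in FIDUCIAL_LABELS:
            raise ValueError(f"unknown fiducial label {label!r}")
        idx = np.flatnonzero(self.labels == label)
        if len(idx) != 1:
            raise ValueError(f"fiducial {label!r} missing")
        return self.points[idx[0]]

    @property
    def has_fiducials(self) -> bool:
        return all(np.any(self.labels == lab) for lab in FIDUCIAL_LABELS)

    def fiducial_array(self) -> np.ndarray:
        """3x3 array of (nasion, lpa, rpa)."""
        return np.stack([self.fiducial(lab) for lab in FIDUCIAL_LABELS])

    def select(self, mask: np.ndarray) -> "HeadPointSet":
        mask = np.asarray(mask, dtype=bool)
        src = None if self.source_points is None else self.source_points[mask]
        return HeadPointSet(self.points[mask], self.labels[mask], self.frame, src)

    def by_label(self, labels: Iterable[str]) -> "HeadPointSet":
        labels = set(labels)
        return self.select(np.array([lab in labels for lab in self.labels]))

    def drop_fiducials(self) -> "HeadPointSet":
        return self.select(~np.isin(self.labels.astype(str), FIDUCIAL_LABELS))

    # -- I/O -----------------------------------------------------------
    def to_frame_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels.astype(str),
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame_df().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, frame: str | None = None) -> "HeadPointSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["x", "y", "z"]].to_numpy(float), df["label"].to_numpy(), frame)

    def to_json(self, path=None) -> str:
        payload = {
            "frame": self.frame,
            "points": [
                {"label": str(lab), "xyz": pt.tolist()}
                for lab, pt in zip(self.labels, self.points)
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def apply_transform(T: RigidTransform, pts):
    """Apply a rigid transform to an array or a :class:`HeadPointSet`.

    Point-set frame tags are checked (when both sides are tagged) and
    updated; labels and metadata are preserved.
    """
    if isinstance(pts, HeadPointSet):
        if (
            pts.frame is not None
            and T.from_frame is not None
            and pts.frame != T.from_frame
        ):
            raise FrameError(
                f"transform expects frame {T.from_frame!r}, points are in {pts.frame!r}"
            )
        new_frame = T.to_frame if T.to_frame is not None else pts.frame
        return HeadPointSet(
            T.apply(pts.points), pts.labels.copy(), new_frame, pts.source_points
        )
    return T.apply(np.asarray(pts, dtype=float))


def fit_rigid_landmarks(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``src`` onto ``dst``.

    Classic Kabsch/Umeyama solution: centroid alignment plus SVD of the
    cross-covariance with reflection correction, minimizing
    sum ||T(src_i) - dst_i||^2.  Requires N >= 3 matched, non-collinear
    landmarks.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValueError("src and dst must be matched N x 3 arrays")
    if len(src) < 3:
        raise DegenerateGeometryError("need at least 3 landmark pairs")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise ValueError("landmarks must be finite")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    # rank of the centered configuration: collinear sets cannot pin rotation
    if np.linalg.matrix_rank(s0, tol=1e-9 * max(1.0, np.abs(s0).max())) < 2:
        raise DegenerateGeometryError("landmark configuration is rank deficient")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = dc - R @ sc
    return RigidTransform.from_rotation_translation(R, t)


def build_head_frame(
    nasion: np.ndarray, lpa: np.ndarray, rpa: np.ndarray
) -> RigidTransform:
    """Device-to-head transform for the Neuromag-style head frame.

    x-axis runs from LPA toward RPA; the origin is the foot of the
    perpendicular dropped from the nasion onto the LPA-RPA line; the
    y-axis points toward the nasion and z = x cross y points up.
    """
    nasion = np.asarray(nasion, dtype=float)
    lpa = np.asarray(lpa, dtype=float)
    rpa = np.asarray(rpa, dtype=float)
    xvec = rpa - lpa
    nx = np.linalg.norm(xvec)
    if nx < 1e-9:
        raise DegenerateGeometryError("LPA and RPA coincide")
    xhat = xvec / nx
    origin = lpa + np.dot(nasion - lpa, xhat) * xhat
    yvec = nasion - origin
    ny = np.linalg.norm(yvec)
    if ny < 1e-9:
        raise DegenerateGeometryError("nasion lies on the LPA-RPA line")
    yhat = yvec / ny
    zhat = np.cross(xhat, yhat)
    A = np.stack([xhat, yhat, zhat])  # rows: head-frame axes in device coords
    return RigidTransform.from_rotation_translation(
        A, -A @ origin, from_frame="device", to_frame="head"
    )
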