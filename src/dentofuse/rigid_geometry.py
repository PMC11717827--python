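"""Rigid transforms, anatomical Euler angles, and the 6-DOF pose deviation.

Anatomical frame (right-handed): X is transversal (toward the patient's
left), Y is vertical (up), Z is sagittal (anterior).  Rotations are named
the way craniofacial analysis names them: pitch about X, yaw about Y, roll
about Z.  The Euler factorisation is intrinsic yaw(Y)-pitch(X)-roll(Z); at
the few-degree deviations a fusion pipeline produces, convention-order
differences are second order, but one convention must be fixed and this is
it.

The accuracy of a fusion is summarised by a :class:`PoseDeviation`: given
an experimental and a reference placement of the maxillary dentition in
the face frame, the relative transform is decomposed into the displacement
of the maxilla's measuring point (the area-weighted surface centroid of
the dentition mesh) and the three anatomical rotation angles, with the
Euclidean distance sqrt(dX^2 + dY^2 + dZ^2) of the translational part.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh_core import TriMesh

__all__ = [
    "RigidTransform",
    "PoseDeviation",
    "compose",
    "invert",
    "from_euler",
    "decompose_rotation",
    "maxilla_center",
    "pose_deviation",
    "absolutize",
]

_ORTHO_TOL = 1e-9


class DegenerateOrientationError(ValueError):
    """Pitch at +/-90 deg: yaw and roll are not separable (gimbal lock)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: p -> rotation @ p + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise ValueError("transform entries must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0); reflections not allowed")
        # re-orthonormalise so downstream checks hold to 1e-9
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def to_json_dict(self) -> list[list[float]]:
        return self.matrix().tolist()

    @classmethod
    def from_json_dict(cls, rows: list[list[float]]) -> "RigidTransform":
        return cls.from_matrix(np.asarray(rows))


@dataclass(frozen=True)
class PoseDeviation:
    """6-DOF deviation of one maxilla placement from a reference.

    dx, dy, dz are the displacement (mm) of the maxilla measuring point
    along the transversal, vertical and sagittal axes; roll, pitch, yaw the
    relative rotation (deg); ``euclidean`` = sqrt(dx^2+dy^2+dz^2), computed
    from the signed components and untouched by absolutization.  ``signed``
    records whether absolute values have been taken.
    """

    dx: float
    dy: float
    dz: float
    roll: float
    pitch: float
    yaw: float
    euclidean: float
    signed: bool = True

    def components(self) -> dict[str, float]:
        return {
            "dx": self.dx,
            "dy": self.dy,
            "dz": self.dz,
            "roll": self.roll,
            "pitch": self.pitch,
            "yaw": self.yaw,
            "euclidean": self.euclidean,
        }


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equal to applying *b* first, then *a*."""
    return RigidTransform(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def invert(t: RigidTransform) -> RigidTransform:
    Rt = t.rotation.T
    return RigidTransform(Rt, -Rt @ t.translation)


def from_euler(roll: float, pitch: float, yaw: float) -> RigidTransform:
    """Rotation-only transform from anatomical angles in degrees.

    Intrinsic yaw(Y) - pitch(X) - roll(Z).
    """
    R = Rotation.from_euler("YXZ", [yaw, pitch, roll], degrees=True).as_matrix()
    return RigidTransform(R, np.zeros(3))


def decompose_rotation(t: RigidTransform) -> tuple[float, float, float]:
    """(roll, pitch, yaw) in degrees of the transform's rotation.

    Raises :class:`DegenerateOrientationError` within 0.01 deg of the
    pitch = +/-90 deg gimbal lock (far outside the small-angle regime of
    craniofacial superimposition).
    """
    import warnings

    rot = Rotation.from_matrix(t.rotation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock; we raise
        yaw, pitch, roll = rot.as_euler("YXZ", degrees=True)
    if abs(abs(pitch) - 90.0) < 1e-2:
        raise DegenerateOrientationError(
            f"pitch {pitch:.3f} deg is at gimbal lock; yaw/roll undefined"
        )
    return float(roll), float(pitch), float(yaw)


def maxilla_center(mesh: TriMesh) -> np.ndarray:
    """Measuring point of a dentition mesh: area-weighted surface centroid.

    Area weighting makes the point invariant under re-triangulation of the
    same surface, unlike a raw vertex mean.
    """
    if mesh.n_faces < 1:
        raise ValueError("cannot take the center of an empty mesh")
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    centroid = (a + b + c) / 3.0
    return (area[:, None] * centroid).sum(axis=0) / area.sum()


def pose_deviation(
    t_exp: RigidTransform, t_ref: RigidTransform, center: np.ndarray
) -> PoseDeviation:
    """Signed 6-DOF deviation of *t_exp* from *t_ref* at *center*.

    Both transforms must map the same source dentition into a common face
    frame; *center* is the maxilla measuring point in that common frame
    (i.e. as placed by the reference transform).  The relative transform
    Delta = t_exp o t_ref^-1 — the motion taking the reference placement
    to the experimental placement, expressed in face-frame axes — is
    evaluated as the displacement of *center* (translations; this equals
    t_exp(c) - t_ref(c) for the source-frame point c) and as its
    anatomical Euler angles (rotations).
    """
    center = np.asarray(center, dtype=np.float64).reshape(3)
    delta = compose(t_exp, invert(t_ref))
    d = delta.apply(center) - center
    roll, pitch, yaw = decompose_rotation(delta)
    return PoseDeviation(
        dx=float(d[0]),
        dy=float(d[1]),
        dz=float(d[2]),
        roll=roll,
        pitch=pitch,
        yaw=yaw,
        euclidean=float(np.linalg.norm(d)),
        signed=True,
    )


def absolutize(d: PoseDeviation) -> PoseDeviation:
    """Componentwise absolute values; idempotent; euclidean unchanged."""
    return replace(
        d,
        dx=abs(d.dx),
        dy=abs(d.dy),
        dz=abs(d.dz),
        roll=abs(d.roll),
        pitch=abs(d.pitch),
        yaw=abs(d.yaw),
        signed=False,
    )
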