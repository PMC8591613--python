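"""Rigid-body transform utilities shared by the simulator and the motion pipeline.

Axis convention (room frame and head frame at the start pose):
X right-left, Y down-up, Z back-forward.

Euler convention: intrinsic Tait-Bryan angles applied yaw (about Y) ->
pitch (about X) -> roll (about Z), in degrees.  Rotation matrices are the
internal representation; Euler angles appear only at the API surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

#: scipy Euler sequence implementing intrinsic yaw -> pitch -> roll
_EULER_SEQ = "YXZ"


def euler_to_matrix(pitch: np.ndarray, yaw: np.ndarray, roll: np.ndarray,
                    degrees: bool = True) -> np.ndarray:
    """Rotation matrices from (pitch, yaw, roll) angle arrays.

    Accepts scalars or equal-length arrays; returns (..., 3, 3).
    """
    pitch, yaw, roll = np.broadcast_arrays(
        np.asarray(pitch, float), np.asarray(yaw, float), np.asarray(roll, float))
    angles = np.stack([yaw, pitch, roll], axis=-1)
    return Rotation.from_euler(_EULER_SEQ, angles.reshape(-1, 3),
                               degrees=degrees).as_matrix().reshape(pitch.shape + (3, 3))


def matrix_to_euler(R: np.ndarray, degrees: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`euler_to_matrix`; returns (pitch, yaw, roll)."""
    R = np.asarray(R, float)
    lead = R.shape[:-2]
    angles = Rotation.from_matrix(R.reshape(-1, 3, 3)).as_euler(_EULER_SEQ, degrees=degrees)
    yaw, pitch, roll = angles[:, 0], angles[:, 1], angles[:, 2]
    return pitch.reshape(lead), yaw.reshape(lead), roll.reshape(lead)


def kabsch(template: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping ``template`` onto ``observed``.

    Solves the orthogonal Procrustes problem without scaling: returns
    (R, t) minimising ``sum_i |R @ template_i + t - observed_i|^2`` with a
    proper rotation (det(R) = +1) enforced, so a reflection-optimal
    configuration is corrected to the nearest proper rotation.

    Parameters
    ----------
    template, observed : (m, 3) arrays of corresponding points, m >= 3.
    """
    template = np.asarray(template, float)
    observed = np.asarray(observed, float)
    if template.shape != observed.shape or template.shape[0] < 3:
        raise ValueError("kabsch needs >= 3 corresponding 3-D points")
    ct = template.mean(axis=0)
    co = observed.mean(axis=0)
    H = (template - ct).T @ (observed - co)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = co - R @ ct
    return R, t


def is_collinear(points: np.ndarray, tol: float = 1e-12) -> bool:
    """True when the point set spans less than a plane's worth of directions."""
    pts = np.asarray(points, float)
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)
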