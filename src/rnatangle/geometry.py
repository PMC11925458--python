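"""Small geometric utilities shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a near-zero vector")
    return v / n


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``points`` (SVD)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def kabsch(mobile: np.ndarray, target: np.ndarray, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with ``mobile @ R.T + t`` least-squares closest to
    ``target``. Proper rotation only (reflections excluded).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    H = (w[:, None] * (mobile - mc)).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between matched coordinate sets without superposition."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt((diff * diff).sum() / len(diff)))


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between matched coordinate sets over rigid motions."""
    R, t = kabsch(a, b)
    return rmsd_fixed(np.asarray(a, float) @ R.T + t, b)


def frame_from_normal(n: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (3x3, rows) whose last row is ``n``."""
    n = unit(np.asarray(n, float))
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(n, helper))
    v = np.cross(n, u)
    return np.vstack([u, v, n])


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``angle`` radians about ``axis``."""
    a = unit(np.asarray(axis, float))
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(a, a)
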