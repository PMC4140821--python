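"""Small geometric helpers shared across modules: deterministic sphere point
sets, Euler/quaternion conversions and rotation utilities."""

from __future__ import annotations

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, near-uniform unit vectors on the sphere (n_points, 3)."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = GOLDEN_ANGLE * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def euler_zyz_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix for z-y-z Euler angles in radians, R = Rz(phi) Ry(theta) Rz(psi)."""
    cf, sf = np.cos(phi), np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    rz1 = np.array([[cf, -sf, 0], [sf, cf, 0], [0, 0, 1.0]])
    ry = np.array([[ct, 0, st], [0, 1.0, 0], [-st, 0, ct]])
    rz2 = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1.0]])
    return rz1 @ ry @ rz2


def axis_angle_to_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) with w >= 0 for a proper rotation matrix."""
    R = np.asarray(R, dtype=float)
    t = np.trace(R)
    if t > 0:
        w = np.sqrt(1.0 + t) / 2.0
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 0.0)) * 2.0
        q = np.empty(4)
        q[1 + i] = s / 4.0
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
        w, x, y, z = q
    q = np.array([w, x, y, z])
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle in radians of a proper rotation matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dedup_rotations(matrices: list[np.ndarray], tol: float = 1e-6) -> list[int]:
    """Indices of unique rotations under quaternion comparison (q ~ -q)."""
    kept: list[int] = []
    quats: list[np.ndarray] = []
    for i, R in enumerate(matrices):
        q = matrix_to_quaternion(R)
        if not any(np.allclose(q, p, atol=tol) for p in quats):
            kept.append(i)
            quats.append(q)
    return kept


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
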