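"""Low-level 3D geometry primitives shared across the package.

Everything here operates on plain ``(N, 3)`` float64 arrays in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "nerf_place",
    "rotation_z",
    "rotation_y",
    "rotation_x",
    "kabsch",
    "superposed_rmsd",
    "euler_zyz",
    "compose_zyz",
    "fibonacci_sphere",
]


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC sign convention, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, theta: float, chi: float) -> np.ndarray:
    """Place atom ``d`` bonded to ``c`` by internal coordinates.

    ``bond`` is the c-d distance (A), ``theta`` the b-c-d angle (deg), and
    ``chi`` the a-b-c-d torsion (deg). Natural extension reference frame.
    """
    theta_r = np.radians(theta)
    chi_r = -np.radians(chi)  # sign flip so the realized a-b-c-d torsion equals chi
    d_local = bond * np.array([
        -np.cos(theta_r),
        np.sin(theta_r) * np.cos(chi_r),
        np.sin(theta_r) * np.sin(chi_r),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def kabsch(mobile: np.ndarray, target: np.ndarray,
           allow_reflection: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns ``(R, t)`` with
    ``R @ mobile.T + t`` best approximating ``target`` rows.

    Proper rotation enforced unless ``allow_reflection``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if allow_reflection:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    return R, t


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of paired coordinate rows."""
    R, t = kabsch(mobile, target)
    moved = mobile @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def euler_zyz(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation matrix as R = Rz(a) @ Ry(b) @ Rz(c), degrees.

    ``b`` is returned in [0, 180]. At the gimbal boundary (b ~ 0 or 180) the
    split between a and c is degenerate; a absorbs the full z-rotation and
    c is set to 0, which keeps a + c (the twist) well defined.
    """
    b = float(np.degrees(np.arccos(np.clip(R[2, 2], -1.0, 1.0))))
    if b < 1e-7 or b > 180.0 - 1e-7:
        a = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
        if b > 90.0:
            # Rz(a) Ry(180) Rz(0) has R[1,0] = sin(a) ... handle explicitly
            a = float(np.degrees(np.arctan2(R[1, 0], -R[0, 0])))
        return a, b, 0.0
    a = float(np.degrees(np.arctan2(R[1, 2], R[0, 2])))
    c = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
    return a, b, c


def compose_zyz(a: float, b: float, c: float) -> np.ndarray:
    """Rebuild the rotation matrix from ZYZ Euler angles in degrees."""
    return rotation_z(a) @ rotation_y(b) @ rotation_z(c)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform grid of ``n`` unit vectors (golden spiral)."""
    if n < 1:
        raise ValueError("grid size must be >= 1")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
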