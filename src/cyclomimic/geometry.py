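"""Rigid-body geometry: Kabsch superposition and backbone dihedrals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation matrix R, translation t, A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of ``moving`` onto ``fixed``.

    Returns the rigid transform minimizing the RMSD between the transformed
    moving points and the fixed points, together with that minimum RMSD.
    Reflections are excluded (determinant forced to +1). Requires at least
    three non-collinear points.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("moving and fixed must be equal-shape (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinear (rank < 2) moving or fixed set -> rotation under-determined
    for X in (P0, Q0):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("points are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p2)
    b1 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    b2 = np.asarray(p4) - np.asarray(p3)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def angular_difference(a: float, b: float) -> float:
    """Smallest absolute circular difference of two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)
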