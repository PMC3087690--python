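"""The rotational (Rot) superposition method — the package's ground truth.

Rot is the classical route: translate both barycenters to the origin, solve
for the optimal proper rotation directly (SVD of the 3x3 covariance with a
determinant sign correction that forbids reflections), apply it, and
evaluate the residual deviation explicitly on the superposed coordinates.
It is always computed in binary64 and serves as the oracle against which
the quaternion pipeline is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import _as_coords
from .errors import CorrespondenceError, EmptyInputError

__all__ = ["RigidTransform", "rmsd_rot", "optimal_rotation", "quaternion_to_rotation"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray     # (3,3) orthogonal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions here")

    def apply(self, coords) -> np.ndarray:
        xyz = _as_coords(coords)
        return xyz @ self.rotation.T + self.translation


def optimal_rotation(centered_a: np.ndarray, centered_b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||R a - b|| over corresponding rows.

    Kabsch construction: SVD of H = A^T B with the sign of the smallest
    singular direction flipped when det would otherwise be -1.  For
    rank-deficient (collinear/planar) input the minimiser is not unique;
    one valid minimiser is returned.
    """
    H = centered_a.T @ centered_b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def rmsd_rot(a, b) -> tuple[float, RigidTransform]:
    """Explicit superposition RMSD plus the rigid transform that realises it.

    Centers both sets, rotates A's centered copy onto B's, and returns the
    deviation sqrt(sum |a'_k - b'_k|^2 / N) measured on the superposed
    coordinates, together with the transform mapping original A coordinates
    onto B's frame.
    """
    A = _as_coords(a)
    B = _as_coords(b)
    if A.shape[0] != B.shape[0]:
        raise CorrespondenceError(f"atom counts differ: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] == 0:
        raise EmptyInputError("empty coordinate sets")
    abar = A.mean(axis=0)
    bbar = B.mean(axis=0)
    Ac = A - abar
    Bc = B - bbar
    R = optimal_rotation(Ac, Bc)
    dev = Ac @ R.T - Bc
    rmsd = float(np.sqrt((dev * dev).sum() / A.shape[0]))
    t = bbar - R @ abar
    return rmsd, RigidTransform(rotation=R, translation=t)


def quaternion_to_rotation(q) -> np.ndarray:
    """Rotation matrix of a unit quaternion (scalar-first convention).

    The input must be a unit 4-vector to within 1e-6; a zero-norm input is
    a domain error.  The dominant eigenvector of the key matrix, fed through
    this map, rotates centered A onto centered B.
    """
    q = np.asarray(q, dtype=np.float64)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    n = np.linalg.norm(q)
    if n == 0:
        raise ValueError("zero-norm quaternion")
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {n} too far from 1")
    w, x, y, z = q / n
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
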