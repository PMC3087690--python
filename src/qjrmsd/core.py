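"""Coordinate data model, single-pass covariance accumulation and the
quaternion RMSD pipeline.

The RMSD after optimal rigid superposition of two conformers A and B with
atoms in 1:1 positional correspondence is obtained without ever rotating
coordinates: accumulate the 3x3 covariance matrix R = sum_k a_k b_k^T of the
barycenter-centered coordinates together with the centered squared norms
gA = sum_k |a_k - abar|^2 and gB likewise, build the symmetric traceless 4x4
quaternion key matrix F from R, and read the answer off its largest
eigenvalue:

    RMSD = sqrt( (gA + gB - 2*lambda_max) / N )

Centering is folded into the accumulation ("single pass"): raw products and
raw sums are gathered in one traversal and the mean term is subtracted at
the end, so the coordinates are fetched exactly once.

Arithmetic widths are governed by a :class:`PrecisionPolicy`.  The ``mixed``
policy accumulates the covariance in 64-bit floats but hands the key matrix
to the eigensolver rounded to 32-bit — the compromise that keeps degenerate
cases accurate while the bulk of the eigensolver work stays in single
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorrespondenceError, EmptyInputError, NumericError

__all__ = [
    "PrecisionPolicy",
    "CoordinateSet",
    "CovarianceSummary",
    "KeyMatrix",
    "accumulate_single_pass",
    "build_key_matrix",
    "rmsd_from_lambda",
    "rmsd_qj",
]

_MODES = ("mixed", "double", "single")


@dataclass(frozen=True)
class PrecisionPolicy:
    """Arithmetic-width contract for the RMSD pipeline.

    mode
        ``"double"``  — every stage in IEEE-754 binary64.
        ``"mixed"``   — covariance accumulation in binary64; the 4x4 key
        matrix is rounded to binary32 on its way into the eigensolver.
        ``"single"``  — every elementary arithmetic result is a binary32
        value (computed on genuine float32 arrays).
    """

    mode: str = "mixed"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown precision mode {self.mode!r}; pick from {_MODES}")

    @property
    def accum_dtype(self) -> np.dtype:
        """dtype used for covariance accumulation."""
        return np.dtype(np.float32 if self.mode == "single" else np.float64)

    @property
    def eig_dtype(self) -> np.dtype:
        """dtype of the key matrix handed to the eigensolver."""
        return np.dtype(np.float64 if self.mode == "double" else np.float32)

    @classmethod
    def mixed(cls) -> "PrecisionPolicy":
        return cls("mixed")

    @classmethod
    def double(cls) -> "PrecisionPolicy":
        return cls("double")

    @classmethod
    def single(cls) -> "PrecisionPolicy":
        return cls("single")


class CoordinateSet:
    """Ordered N x 3 atomic coordinates (Angstrom) of one structure.

    Atom order *is* the correspondence: atom k of one set is always compared
    with atom k of another.  No name or element matching is performed.
    """

    __slots__ = ("coords", "label")

    def __init__(self, coords, label: str = "") -> None:
        arr = np.ascontiguousarray(coords, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got shape {arr.shape}")
        if arr.shape[0] == 0:
            raise EmptyInputError("coordinate set with zero atoms")
        if not np.isfinite(arr).all():
            raise NumericError(f"non-finite coordinates in {label or 'coordinate set'}")
        self.coords = arr
        self.label = label

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"CoordinateSet(n_atoms={self.n_atoms}, label={self.label!r})"


@dataclass(frozen=True)
class CovarianceSummary:
    """Everything one pair comparison needs from the coordinates.

    R is the 3x3 covariance of the centered coordinates (A^2); gA and gB are
    the centered squared norms of each set; all three are invariant under
    rigid translation of either input.
    """

    R: np.ndarray
    gA: float
    gB: float
    n_atoms: int


@dataclass(frozen=True)
class KeyMatrix:
    """The symmetric, traceless 4x4 quaternion key matrix (A^2)."""

    F: np.ndarray

    def __post_init__(self) -> None:
        F = self.F
        if F.shape != (4, 4):
            raise ValueError(f"key matrix must be 4x4, got {F.shape}")
        if not np.isfinite(F).all():
            raise NumericError("non-finite key matrix")


def _as_coords(x) -> np.ndarray:
    if isinstance(x, CoordinateSet):
        return x.coords
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected (N, 3) coordinates, got shape {arr.shape}")
    return arr


def accumulate_single_pass(a, b, policy: PrecisionPolicy = PrecisionPolicy()) -> CovarianceSummary:
    """One-traversal accumulation of covariance and centered norms.

    Gathers ``sum a_k b_k^T``, ``sum a_k``, ``sum b_k``, ``sum |a_k|^2`` and
    ``sum |b_k|^2`` from a single pass over the paired coordinates, then
    subtracts the mean terms:

        R  = sum a b^T - (sum a)(sum b)^T / N
        gA = sum |a|^2 - |sum a|^2 / N          (gB analogously)

    equivalent (to the policy's precision) to first translating both
    barycenters to the origin.
    """
    A = _as_coords(a)
    B = _as_coords(b)
    if A.shape[0] != B.shape[0]:
        raise CorrespondenceError(
            f"atom counts differ: {A.shape[0]} vs {B.shape[0]}"
        )
    n = A.shape[0]
    if n == 0:
        raise EmptyInputError("empty coordinate sets")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise NumericError("non-finite coordinates")

    dt = policy.accum_dtype
    A = A.astype(dt, copy=False)
    B = B.astype(dt, copy=False)

    sab = A.T @ B                    # nine raw products, summed
    sa = A.sum(axis=0)
    sb = B.sum(axis=0)
    qa = (A * A).sum()
    qb = (B * B).sum()

    R = sab - np.outer(sa, sb) / n
    gA = qa - (sa @ sa) / n
    gB = qb - (sb @ sb) / n
    # rounding (or single-precision cancellation) can leave a tiny negative
    gA = max(float(gA), 0.0)
    gB = max(float(gB), 0.0)
    return CovarianceSummary(R=R, gA=gA, gB=gB, n_atoms=n)


def build_key_matrix(s: CovarianceSummary, policy: PrecisionPolicy = PrecisionPolicy()) -> KeyMatrix:
    """Assemble the symmetric 4x4 key matrix from a covariance summary.

    The entries follow the standard quaternion formulation; the matrix is
    traceless by construction and stored exactly symmetric.  Under the
    ``mixed`` policy the entries are rounded to binary32 on output.
    """
    R = s.R
    if not np.isfinite(R).all():
        raise NumericError("non-finite covariance matrix")
    F = np.empty((4, 4), dtype=R.dtype)
    F[0, 0] = R[0, 0] + R[1, 1] + R[2, 2]
    F[1, 1] = R[0, 0] - R[1, 1] - R[2, 2]
    F[2, 2] = -R[0, 0] + R[1, 1] - R[2, 2]
    F[3, 3] = -R[0, 0] - R[1, 1] + R[2, 2]
    F[0, 1] = F[1, 0] = R[1, 2] - R[2, 1]
    F[0, 2] = F[2, 0] = R[2, 0] - R[0, 2]
    F[0, 3] = F[3, 0] = R[0, 1] - R[1, 0]
    F[1, 2] = F[2, 1] = R[0, 1] + R[1, 0]
    F[1, 3] = F[3, 1] = R[0, 2] + R[2, 0]
    F[2, 3] = F[3, 2] = R[1, 2] + R[2, 1]
    return KeyMatrix(F.astype(policy.eig_dtype, copy=False))


def rmsd_from_lambda(gA, gB, lambda_max, n_atoms, policy: PrecisionPolicy | None = None):
    """RMSD from the maximum eigenvalue: sqrt(max(0, (gA+gB-2*lmax)/N)).

    The radicand is clamped at zero before the square root — rounding can
    drive it slightly negative for (near-)identical structures.  Accepts
    scalars or equally-shaped arrays.  Under the ``single`` policy the
    assembly itself is carried in binary32.
    """
    n = np.asarray(n_atoms)
    if np.any(n < 1):
        raise ValueError(f"n_atoms must be >= 1, got {n_atoms}")
    dt = np.float32 if (policy is not None and policy.mode == "single") else np.float64
    gA = np.asarray(gA, dtype=dt)
    gB = np.asarray(gB, dtype=dt)
    lam = np.asarray(lambda_max, dtype=dt)
    radicand = (gA + gB - 2.0 * lam) / n
    out = np.sqrt(np.maximum(radicand, 0.0))
    return float(out) if out.ndim == 0 else out.astype(np.float64)


def rmsd_qj(a, b, policy: PrecisionPolicy = PrecisionPolicy()) -> float:
    """Quaternion-Jacobi RMSD of two corresponding coordinate sets.

    Full pipeline: single-pass covariance -> key matrix -> cyclic-Jacobi
    eigenvalues -> RMSD from lambda_max.  Deterministic for fixed inputs and
    policy, and symmetric in its arguments to within the policy's rounding.
    """
    from .eigen import jacobi_eig4

    s = accumulate_single_pass(a, b, policy)
    F = build_key_matrix(s, policy)
    res = jacobi_eig4(F, policy=policy)
    return rmsd_from_lambda(s.gA, s.gB, res.eigenvalues[0], s.n_atoms, policy)
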