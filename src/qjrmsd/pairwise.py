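"""All-pairs RMSD similarity-matrix engine.

Only the upper triangle is ever computed (the matrix is symmetric with a
zero diagonal), stored condensed in row-major order: the pair (i, j) with
i < j lives at index ``i*M - i*(i+1)/2 + (j - i - 1)``.  Backends: the
quaternion-Jacobi pipeline (qj, the production method), the
characteristic-polynomial Newton solver (qcp), shifted power iteration
(qp), and the explicit rotational method (rot).  Key matrices are built
pair by pair and eigen-solved in batches; batching is a cache-friendliness
knob only and never changes results.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .core import (CoordinateSet, PrecisionPolicy, accumulate_single_pass,
                   build_key_matrix, rmsd_from_lambda)
from .errors import EnsembleError
from . import eigen as _eigen
from .rotational import rmsd_rot

__all__ = [
    "Ensemble",
    "SimilarityMatrix",
    "BenchmarkReport",
    "pair_index",
    "compute_matrix",
    "benchmark_methods",
    "METHODS",
]

METHODS = ("qj", "qcp", "qp", "rot")


class Ensemble:
    """Ordered list of M structures with identical atom counts."""

    def __init__(self, coords, labels=None) -> None:
        arr = np.ascontiguousarray(coords, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise EnsembleError(f"ensemble coords must be (M, N, 3), got {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise EnsembleError("ensemble needs at least one member and one atom")
        if not np.isfinite(arr).all():
            raise EnsembleError("non-finite coordinates in ensemble")
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        if len(labels) != arr.shape[0]:
            raise EnsembleError("label count does not match member count")
        self.coords = arr
        self.labels = list(labels)

    @classmethod
    def from_coordsets(cls, structures) -> "Ensemble":
        structures = list(structures)
        if not structures:
            raise EnsembleError("empty ensemble")
        n0 = structures[0].n_atoms
        for k, s in enumerate(structures):
            if s.n_atoms != n0:
                raise EnsembleError(
                    f"member {k} ({s.label or 'unnamed'}) has {s.n_atoms} atoms, "
                    f"expected {n0}"
                )
        coords = np.stack([s.coords for s in structures])
        labels = [s.label or str(i) for i, s in enumerate(structures)]
        return cls(coords, labels)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, i: int) -> CoordinateSet:
        return CoordinateSet(self.coords[i], self.labels[i])


@dataclass
class SimilarityMatrix:
    """Condensed upper-triangle store of all-pairs RMSDs (A)."""

    condensed: np.ndarray          # (M*(M-1)/2,) float64
    M: int
    method: str
    policy: str
    labels: list[str] = field(default_factory=list)
    fallback_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        want = self.M * (self.M - 1) // 2
        if self.condensed.shape != (want,):
            raise EnsembleError(
                f"condensed length {self.condensed.shape} != M(M-1)/2 = {want}"
            )

    def get(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        return float(self.condensed[pair_index(i, j, self.M)])

    def to_square(self) -> np.ndarray:
        sq = np.zeros((self.M, self.M))
        iu = np.triu_indices(self.M, k=1)
        sq[iu] = self.condensed
        return sq + sq.T


def pair_index(i: int, j: int, M: int) -> int:
    """Condensed offset of pair (i, j), i < j, in an M-member matrix."""
    if not (0 <= i < j < M):
        raise IndexError(f"need 0 <= i < j < M, got i={i}, j={j}, M={M}")
    return i * M - i * (i + 1) // 2 + (j - i - 1)


def _pair_iter(M: int):
    for i in range(M - 1):
        for j in range(i + 1, M):
            yield i, j


def _solve_batch(Fb: np.ndarray, gsum: np.ndarray, method: str):
    """lambda_max and convergence flags for a stack of key matrices."""
    if method == "qj":
        vals, _, _, conv = _eigen.jacobi_eig4_batch(Fb)
        return vals[:, 0], conv
    if method == "qcp":
        lam, conv, _ = _eigen.qcp_lambda_max_batch(Fb, gsum)
        return lam, conv
    if method == "qp":
        lam, conv, _ = _eigen.power_lambda_max_batch(Fb)
        return lam, conv
    raise ValueError(f"unknown eigen backend {method!r}")


def compute_matrix(ensemble: Ensemble, method: str = "qj",
                   policy: PrecisionPolicy = PrecisionPolicy(),
                   batch_size: int = 4096) -> SimilarityMatrix:
    """All-pairs RMSD over an ensemble, upper triangle only.

    Each of the M(M-1)/2 pairs is evaluated exactly once with the selected
    backend; the diagonal and duplicate (j, i) comparisons are never
    computed.  Results are independent of ``batch_size`` and of evaluation
    order.  Should an iterative backend fail to converge on a pair, the
    entry is recomputed with the rotational method and the pair recorded in
    ``fallback_pairs``.
    """
    M = len(ensemble)
    if M < 2:
        raise EnsembleError("need at least 2 structures for a similarity matrix")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")

    n_pairs = M * (M - 1) // 2
    out = np.empty(n_pairs, dtype=np.float64)
    fallbacks: list[tuple[int, int]] = []
    X = ensemble.coords

    if method == "rot":
        for k, (i, j) in enumerate(_pair_iter(M)):
            out[k] = rmsd_rot(X[i], X[j])[0]
        return SimilarityMatrix(out, M, method, policy.mode, list(ensemble.labels))

    pairs = list(_pair_iter(M))
    for start in range(0, n_pairs, batch_size):
        chunk = pairs[start:start + batch_size]
        B = len(chunk)
        Fb = np.empty((B, 4, 4), dtype=policy.eig_dtype)
        gA = np.empty(B)
        gB = np.empty(B)
        for k, (i, j) in enumerate(chunk):
            s = accumulate_single_pass(X[i], X[j], policy)
            Fb[k] = build_key_matrix(s, policy).F
            gA[k] = s.gA
            gB[k] = s.gB
        lam, conv = _solve_batch(Fb, gA + gB, method)
        vals = rmsd_from_lambda(gA, gB, lam, ensemble.n_atoms, policy)
        if not conv.all():
            for k in np.flatnonzero(~conv):
                i, j = chunk[k]
                vals[k] = rmsd_rot(X[i], X[j])[0]
                fallbacks.append((i, j))
        out[start:start + B] = vals
    return SimilarityMatrix(out, M, method, policy.mode, list(ensemble.labels),
                            fallbacks)


@dataclass
class BenchmarkReport:
    """Wall-time and cross-method agreement summary for one ensemble."""

    timings: dict                  # method -> list of per-repeat seconds
    means: dict                    # method -> mean seconds
    ratios: dict                   # method -> mean / fastest mean ({} if single method)
    max_discrepancy: dict          # "m1/m2" -> max |delta RMSD| (A)


def benchmark_methods(ensemble: Ensemble, methods=("qj", "qcp", "qp", "rot"),
                      repeats: int = 5,
                      policy: PrecisionPolicy = PrecisionPolicy()) -> BenchmarkReport:
    """Time the full-matrix computation per backend and compare results.

    Each backend runs ``repeats`` times; mean wall times, ratios relative to
    the fastest backend, and the maximum entrywise RMSD discrepancy between
    every backend pair are reported.  Timing values are hardware-dependent
    bookkeeping; the discrepancies are the scientific content.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    methods = list(methods)
    timings: dict = {m: [] for m in methods}
    matrices: dict = {}
    for m in methods:
        for _ in range(repeats):
            t0 = time.perf_counter()
            mat = compute_matrix(ensemble, method=m, policy=policy)
            timings[m].append(time.perf_counter() - t0)
        matrices[m] = mat
    means = {m: float(np.mean(ts)) for m, ts in timings.items()}
    if len(methods) >= 2:
        fastest = min(means.values())
        ratios = {m: means[m] / fastest for m in methods}
    else:
        ratios = {}
    disc = {}
    for a in range(len(methods)):
        for b in range(a + 1, len(methods)):
            ma, mb = methods[a], methods[b]
            disc[f"{ma}/{mb}"] = float(
                np.abs(matrices[ma].condensed - matrices[mb].condensed).max()
            )
    return BenchmarkReport(timings, means, ratios, disc)
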