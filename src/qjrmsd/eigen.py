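"""Eigenvalue kernels for the symmetric 4x4 key matrix.

Three routes to lambda_max are provided:

``jacobi_eig4``
    A cyclic-Jacobi solver specialised to symmetric 4x4 input, sweeping the
    six upper-triangle pivots in a fixed raster order.  This is the
    production method: it converges stably even when run entirely in
    binary32, which is what makes the mixed-precision RMSD pipeline viable.

``qcp_lambda_max``
    Newton-Raphson on the quartic characteristic polynomial, started from
    the analytic upper bound (gA+gB)/2.  Fast in double precision, but
    known to lose accuracy or stall in single precision; it therefore
    reports a convergence flag rather than failing silently.

``power_lambda_max``
    Power iteration on the Gershgorin-shifted matrix, with a Rayleigh
    quotient estimate.

All three have batched variants operating on stacks of matrices; the
per-matrix arithmetic of the batched kernels is identical to the scalar
path (frozen matrices receive exact identity updates), so results are
independent of how work is batched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import KeyMatrix, PrecisionPolicy
from .errors import NumericError

__all__ = [
    "EigenResult",
    "LambdaResult",
    "jacobi_eig4",
    "jacobi_eig4_batch",
    "qcp_lambda_max",
    "qcp_lambda_max_batch",
    "power_lambda_max",
    "power_lambda_max_batch",
]

# fixed upper-triangle raster pivot order
_PIVOTS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
# the two indices untouched by each pivot rotation
_REST = {(0, 1): (2, 3), (0, 2): (1, 3), (0, 3): (1, 2),
         (1, 2): (0, 3), (1, 3): (0, 2), (2, 3): (0, 1)}

#: default relative convergence tolerances, per arithmetic width
JACOBI_TOL = {np.dtype(np.float32): 1e-7, np.dtype(np.float64): 1e-12}
QCP_TOL = {np.dtype(np.float32): 1e-6, np.dtype(np.float64): 1e-12}
POWER_TOL = {np.dtype(np.float32): 1e-7, np.dtype(np.float64): 1e-13}

#: pivots with |F_pq| below _TINY * ||F|| are skipped (guards 0/0 in theta)
_TINY = 1e-30


@dataclass(frozen=True)
class EigenResult:
    """Eigenvalues (descending) and, optionally, the dominant eigenvector."""

    eigenvalues: np.ndarray          # (4,) float64, descending
    dominant_vector: np.ndarray | None  # unit quaternion for lambda_max
    iterations: int                  # full sweeps performed
    converged: bool


class LambdaResult(NamedTuple):
    value: float
    converged: bool
    iterations: int


def _check_symmetric(F: np.ndarray) -> np.ndarray:
    if F.shape[-2:] != (4, 4):
        raise NumericError(f"expected 4x4 matrix, got shape {F.shape}")
    if not np.isfinite(F).all():
        raise NumericError("non-finite matrix entries")
    if not np.array_equal(F, np.swapaxes(F, -1, -2)):
        raise NumericError("matrix is not exactly symmetric")
    return F


def _off_norm(F: np.ndarray) -> np.ndarray:
    """sqrt(sum of squared off-diagonal upper-triangle entries), float64."""
    G = F.astype(np.float64, copy=False)
    s = np.zeros(F.shape[0], dtype=np.float64)
    for p, q in _PIVOTS:
        s += G[:, p, q] ** 2
    return np.sqrt(s)


def jacobi_eig4_batch(F, tol: float | None = None, max_sweeps: int = 50,
                      vectors: bool = False, return_matrix: bool = False):
    """Cyclic-Jacobi on a stack of symmetric 4x4 matrices.

    Parameters mirror :func:`jacobi_eig4`.  Returns ``(eigenvalues (K,4)
    descending float64, dominant_vectors (K,4) or None, sweeps (K,),
    converged (K,))``.  Matrices that have met the convergence criterion are
    frozen bit-exactly while the rest of the batch continues, so per-matrix
    results do not depend on batch composition.
    """
    F = np.array(F, copy=True)
    dt = F.dtype
    if tol is None:
        tol = JACOBI_TOL[dt]
    K = F.shape[0]

    norm0 = np.sqrt((F.astype(np.float64) ** 2).sum(axis=(1, 2)))
    thresh = tol * norm0
    skip = _TINY * norm0

    converged = _off_norm(F) <= thresh
    sweeps = np.zeros(K, dtype=np.int64)
    V = np.broadcast_to(np.eye(4, dtype=dt), (K, 4, 4)).copy() if vectors else None

    one = dt.type(1)
    zero = dt.type(0)

    for _ in range(max_sweeps):
        if converged.all():
            break
        frozen = converged.copy()
        for (p, q) in _PIVOTS:
            apq = F[:, p, q]
            active = (~frozen) & (np.abs(apq.astype(np.float64)) > skip)
            app = F[:, p, p].copy()
            aqq = F[:, q, q].copy()
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                theta = (aqq - app) / (2 * apq)
                sgn = np.where(theta < 0, -one, one)
                t = sgn / (np.abs(theta) + np.sqrt(theta * theta + one))
            t = np.where(active, t, zero)
            c = one / np.sqrt(t * t + one)
            s = t * c
            tau = s / (one + c)
            s = np.where(active, s, zero)
            tau = np.where(active, tau, zero)

            F[:, p, p] = app - t * apq
            F[:, q, q] = aqq + t * apq
            F[:, p, q] = np.where(active, zero, apq)
            F[:, q, p] = F[:, p, q]
            for k in _REST[(p, q)]:
                akp = F[:, k, p].copy()
                akq = F[:, k, q].copy()
                nkp = akp - s * (akq + tau * akp)
                nkq = akq + s * (akp - tau * akq)
                F[:, k, p] = nkp
                F[:, p, k] = nkp
                F[:, k, q] = nkq
                F[:, q, k] = nkq
            if V is not None:
                for k in range(4):
                    vkp = V[:, k, p].copy()
                    vkq = V[:, k, q].copy()
                    V[:, k, p] = vkp - s * (vkq + tau * vkp)
                    V[:, k, q] = vkq + s * (vkp - tau * vkq)
        sweeps[~frozen] += 1
        converged = frozen | (_off_norm(F) <= thresh)

    vals = np.diagonal(F, axis1=1, axis2=2).astype(np.float64)
    order = np.argsort(-vals, axis=1, kind="stable")
    vals = np.take_along_axis(vals, order, axis=1)
    dom = None
    if V is not None:
        dom = np.take_along_axis(
            V.astype(np.float64), order[:, 0][:, None, None].repeat(4, axis=1), axis=2
        )[:, :, 0]
        dom /= np.linalg.norm(dom, axis=1, keepdims=True)
        # deterministic sign: largest-magnitude component positive
        lead = np.take_along_axis(dom, np.abs(dom).argmax(axis=1)[:, None], axis=1)
        dom *= np.where(lead < 0, -1.0, 1.0)
    if return_matrix:
        return vals, dom, sweeps, converged, F
    return vals, dom, sweeps, converged


def jacobi_eig4(F, tol: float | None = None, max_sweeps: int = 50,
                policy: PrecisionPolicy | None = None,
                vectors: bool = False) -> EigenResult:
    """Eigenvalues of one symmetric 4x4 matrix by fixed-order cyclic Jacobi.

    Sweeps annihilate the six upper-triangle pivots in raster order until
    ``off(F) <= tol * ||F||_F`` (Frobenius norm of the input) or
    ``max_sweeps`` is reached.  ``tol`` defaults per arithmetic width
    (1e-7 for binary32, 1e-12 for binary64).  If ``policy`` is given the
    matrix is first cast to the policy's eigensolver dtype.
    """
    A = F.F if isinstance(F, KeyMatrix) else np.asarray(F)
    _check_symmetric(A)
    if policy is not None:
        A = A.astype(policy.eig_dtype, copy=False)
    if A.dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        A = A.astype(np.float64)
    vals, dom, sweeps, conv = jacobi_eig4_batch(
        A[None], tol=tol, max_sweeps=max_sweeps, vectors=vectors
    )
    return EigenResult(
        eigenvalues=vals[0],
        dominant_vector=None if dom is None else dom[0],
        iterations=int(sweeps[0]),
        converged=bool(conv[0]),
    )


# ---------------------------------------------------------------------------
# Q-CP: Newton-Raphson on the characteristic polynomial


def _char_poly_coeffs(F: np.ndarray):
    """Coefficients (c3, c2, c1, c0) of det(lambda*I - F), in F's dtype.

    For a genuine key matrix trace(F) = 0 so the cubic term vanishes; the
    general formulas are kept so arbitrary symmetric input is handled.
    """
    tr1 = np.trace(F, axis1=-2, axis2=-1)
    F2 = F @ F
    tr2 = np.trace(F2, axis1=-2, axis2=-1)
    tr3 = np.trace(F2 @ F, axis1=-2, axis2=-1)
    c3 = -tr1
    c2 = (tr1 * tr1 - tr2) / 2
    c1 = -(tr1 * tr1 * tr1 - 3 * tr1 * tr2 + 2 * tr3) / 6
    c0 = np.linalg.det(F)
    return c3, c2, c1, c0


def qcp_lambda_max_batch(F, gsum, tol: float | None = None, max_iter: int = 50):
    """Vectorised Q-CP Newton solve; see :func:`qcp_lambda_max`.

    ``gsum`` is gA+gB per matrix.  Returns ``(lambda (K,) float64,
    converged (K,), iterations (K,))``.
    """
    F = np.asarray(F)
    dt = F.dtype
    if tol is None:
        tol = QCP_TOL[dt]
    gsum = np.asarray(gsum, dtype=dt)
    c3, c2, c1, c0 = _char_poly_coeffs(F)
    lam0 = gsum / 2
    lam = lam0.copy()
    K = F.shape[0]
    converged = np.zeros(K, dtype=bool)
    failed = np.zeros(K, dtype=bool)     # detected stall/divergence: frozen
    iters = np.zeros(K, dtype=np.int64)
    # degenerate all-zero matrices: the root is 0, immediately converged
    zero_mat = (np.abs(F).sum(axis=(1, 2)) == 0)
    converged |= zero_mat
    lam = np.where(zero_mat, dt.type(0), lam)
    step_ok = np.abs(lam0.astype(np.float64)) * tol

    for _ in range(max_iter):
        active = ~converged & ~failed
        if not active.any():
            break
        p = (((lam + c3) * lam + c2) * lam + c1) * lam + c0
        dp = ((4 * lam + 3 * c3) * lam + 2 * c2) * lam + c1
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            delta = p / dp
        bad = ~np.isfinite(delta)
        delta = np.where(bad | ~active, dt.type(0), delta)
        lam = lam - delta
        iters[active] += 1
        converged |= active & ~bad & (np.abs(delta.astype(np.float64)) <= step_ok)
        failed |= active & (bad | ~np.isfinite(lam.astype(np.float64)))
    lam = np.where(np.isfinite(lam), lam, lam0)
    return lam.astype(np.float64), converged, iters


def qcp_lambda_max(F, gA: float, gB: float, tol: float | None = None,
                   max_iter: int = 50,
                   policy: PrecisionPolicy | None = None) -> LambdaResult:
    """Largest real root of F's characteristic polynomial via Newton-Raphson.

    The quartic is evaluated by Horner's rule in the matrix dtype; the
    iteration starts from the analytic upper bound lambda_0 = (gA+gB)/2 and
    stops when ``|delta| <= tol * |lambda_0|``.  Non-convergence (stall,
    divergence, non-finite iterates — expected for some inputs in binary32)
    is *flagged*, never silently returned as a good value.
    """
    A = F.F if isinstance(F, KeyMatrix) else np.asarray(F)
    _check_symmetric(A)
    if policy is not None:
        A = A.astype(policy.eig_dtype, copy=False)
    lam, conv, iters = qcp_lambda_max_batch(A[None], [gA + gB], tol=tol, max_iter=max_iter)
    return LambdaResult(float(lam[0]), bool(conv[0]), int(iters[0]))


# ---------------------------------------------------------------------------
# Q-P: shifted power iteration

# deterministic, direction-free start vector (no symmetry with coordinate axes)
_V0 = np.array([0.5377671, 0.2706503, 0.1876351, 0.7745321])


def power_lambda_max_batch(F, tol: float | None = None, max_iter: int = 10000):
    """Vectorised shifted power iteration; see :func:`power_lambda_max`."""
    F = np.asarray(F)
    dt = F.dtype
    if tol is None:
        tol = POWER_TOL[dt]
    K = F.shape[0]
    sigma = np.abs(F).sum(axis=2).max(axis=1)          # Gershgorin row-sum bound
    M = F + sigma[:, None, None] * np.eye(4, dtype=dt)
    v = np.broadcast_to(_V0.astype(dt), (K, 4)).copy()
    est = np.full(K, np.inf, dtype=np.float64)
    converged = np.zeros(K, dtype=bool)
    iters = np.zeros(K, dtype=np.int64)
    zero_mat = (np.abs(F).sum(axis=(1, 2)) == 0) & (sigma == 0)
    converged |= zero_mat

    for _ in range(max_iter):
        if converged.all():
            break
        active = ~converged
        w = np.einsum("kij,kj->ki", M, v)
        new_est = np.einsum("ki,ki->k", v, w).astype(np.float64)
        nw = np.sqrt(np.einsum("ki,ki->k", w, w))
        safe = nw > 0
        v_next = np.where((active & safe)[:, None], w / np.where(nw == 0, 1, nw)[:, None], v)
        v = v_next.astype(dt)
        diff = np.abs(new_est - est)
        scale = np.abs(new_est) + sigma.astype(np.float64)
        done = diff <= tol * np.maximum(scale, 1e-300)
        est = np.where(active, new_est, est)
        iters[active] += 1
        converged |= active & done
        converged |= active & ~safe          # w vanished: F maps v to 0
    lam = est - sigma.astype(np.float64)
    lam = np.where(np.isfinite(lam), lam, 0.0)
    return lam, converged, iters


def power_lambda_max(F, tol: float | None = None, max_iter: int = 10000) -> LambdaResult:
    """lambda_max by power iteration on the Gershgorin-shifted matrix.

    The shift sigma (maximum absolute row sum) makes the algebraically
    largest eigenvalue of F the dominant eigenvalue of F + sigma*I; the
    Rayleigh-quotient estimate minus sigma is returned.  Convergence is
    declared when successive estimates differ by <= tol*(|estimate|+sigma).
    """
    A = F.F if isinstance(F, KeyMatrix) else np.asarray(F)
    _check_symmetric(A)
    lam, conv, iters = power_lambda_max_batch(A[None], tol=tol, max_iter=max_iter)
    return LambdaResult(float(lam[0]), bool(conv[0]), int(iters[0]))
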