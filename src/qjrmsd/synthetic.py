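"""Deterministic synthetic structure ensembles for testing and benchmarks.

Real decoy sets for small proteins (70-140 residues, ensembles of hundreds
to thousands of members, spanning near-identical to highly divergent pairs)
are emulated by three pieces:

* a compact self-avoiding random walk standing in for a folded chain
  (fixed 3.8 A virtual-bond step, 3.0 A excluded volume, confined to a
  sphere sized for protein-like packing density);
* a perturbation operator adding isotropic Gaussian coordinate noise and an
  optional random rigid motion, spanning the near-duplicate-to-divergent
  range by varying the noise scale;
* a catalogue of small degenerate fixtures (identical, translated, rotated,
  collinear, planar, mirrored-planar, near-identical, large-coordinate
  offset) that stress exactly the cases where arithmetic precision matters.

Everything is bit-reproducible for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .core import CoordinateSet
from .errors import GenerationError
from .pairwise import Ensemble
from .rotational import quaternion_to_rotation

__all__ = [
    "GeneratorConfig",
    "ATOMS_PER_RESIDUE",
    "make_base_structure",
    "perturb",
    "make_ensemble",
    "pair_suite",
    "degenerate_fixtures",
    "DegeneratePair",
]

#: pseudo-atoms per residue; 8 approximates small-protein all-atom counts
ATOMS_PER_RESIDUE = 8
#: virtual bond length between consecutive pseudo-atoms (A)
STEP = 3.8
#: excluded-volume cutoff between non-consecutive pseudo-atoms (A)
MIN_DIST = 3.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Ensemble recipe: one base fold plus noisy, rigidly moved replicas."""

    n_residues: int = 100
    ensemble_size: int = 100
    noise_sd: float = 1.0          # per-coordinate Gaussian sd (A)
    rigid_motion: bool = True
    seed: int = 0
    atoms_per_residue: int = ATOMS_PER_RESIDUE


def _serpentine_guide(n: int) -> np.ndarray:
    """Space-filling boustrophedon path through a cubic lattice.

    Consecutive guide points are exactly one lattice spacing (STEP) apart
    and non-consecutive points at least STEP apart, so the guide itself is
    a feasible compact self-avoiding chain the random walk can shadow.
    """
    m = int(np.ceil(n ** (1.0 / 3.0)))
    idx = []
    xdir = 1
    for z in range(m):
        yr = range(m) if z % 2 == 0 else range(m - 1, -1, -1)
        for y in yr:
            xr = range(m) if xdir == 1 else range(m - 1, -1, -1)
            for x in xr:
                idx.append((x, y, z))
            xdir = -xdir
            if len(idx) >= n:
                break
        if len(idx) >= n:
            break
    guide = STEP * np.asarray(idx[:n], dtype=np.float64)
    return guide - guide.mean(axis=0)


def make_base_structure(n_residues: int, seed: int,
                        atoms_per_residue: int = ATOMS_PER_RESIDUE) -> CoordinateSet:
    """Compact self-avoiding random-walk pseudo-chain.

    ``n_residues * atoms_per_residue`` points, consecutive points exactly
    ``STEP`` apart, non-consecutive points no closer than ``MIN_DIST``.
    Candidate step directions are drawn at random and rejected on
    excluded-volume clashes; to make the chain pack like a globule rather
    than an expanded coil, the draw is biased toward a space-filling
    serpentine guide path, giving protein-like compactness at all chain
    lengths.  The walk backtracks when it jams; bounded restarts turn
    pathological cases into a :class:`GenerationError`.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    n = n_residues * atoms_per_residue
    rng = np.random.default_rng(seed)
    guide = _serpentine_guide(n)
    for _ in range(20):                      # bounded fresh restarts
        pts = _grow_chain(n, guide, rng)
        if pts is not None:
            return CoordinateSet(pts, label=f"base-r{n_residues}-s{seed}")
    raise GenerationError(f"could not grow a compact {n}-atom chain")


def _grow_chain(n: int, guide: np.ndarray, rng: np.random.Generator):
    """One attempt at the guided self-avoiding walk; None if it jams."""
    pts = np.empty((n, 3))
    pts[0] = guide[0]
    i = 1
    backtracks = 0
    batch = 32
    while i < n:
        placed = False
        prev = pts[i - 1]
        w = guide[i] - prev
        wn = np.linalg.norm(w)
        pull = (w / wn) * min(1.5, 0.35 + 0.25 * wn / STEP) if wn > 0 else 0.0
        for _ in range(4):  # up to 4 * batch candidate directions
            u = rng.normal(size=(batch, 3)) + pull
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            cand = prev + STEP * u
            if i >= 2:
                d2 = ((cand[:, None, :] - pts[None, : i - 1, :]) ** 2).sum(axis=2)
                ok = (d2 >= MIN_DIST * MIN_DIST).all(axis=1)
            else:
                ok = np.ones(batch, dtype=bool)
            hit = np.flatnonzero(ok)
            if hit.size:
                # among clash-free candidates, follow the guide most closely
                best = hit[np.argmin(((cand[hit] - guide[i]) ** 2).sum(axis=1))]
                pts[i] = cand[best]
                i += 1
                placed = True
                break
        if not placed:
            backtracks += 1
            if backtracks > 100:
                return None
            i = max(1, i - int(rng.integers(2, 12)))
    return pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return quaternion_to_rotation(q)


def perturb(base: CoordinateSet, noise_sd: float, rigid_motion: bool,
            seed: int) -> CoordinateSet:
    """Noisy replica of ``base``: Gaussian displacement then rigid motion.

    Isotropic Gaussian noise of standard deviation ``noise_sd`` is added to
    every coordinate; if ``rigid_motion`` a uniformly random proper rotation
    and a translation drawn from [-50, 50] A per axis follow.  With
    ``noise_sd = 0`` the replica is exactly superposable on the base.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    xyz = base.coords.copy()
    if noise_sd > 0:
        xyz = xyz + rng.normal(0.0, noise_sd, size=xyz.shape)
    if rigid_motion:
        R = _random_rotation(rng)
        t = rng.uniform(-50.0, 50.0, size=3)
        xyz = xyz @ R.T + t
    return CoordinateSet(xyz, label=f"{base.label}|sd{noise_sd:g}-s{seed}")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def make_ensemble(config: GeneratorConfig) -> Ensemble:
    """Ensemble of noisy replicas of one base fold, per ``config``."""
    base = make_base_structure(config.n_residues, config.seed,
                               config.atoms_per_residue)
    seeds = _child_seeds(config.seed + 1, config.ensemble_size)
    members = [
        perturb(base, config.noise_sd, config.rigid_motion, int(s))
        for s in seeds
    ]
    return Ensemble.from_coordsets(members)


def pair_suite(n_pairs: int, seed: int,
               noise_levels: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
               n_res_range: tuple[int, int] = (70, 140),
               pairs_per_base: int = 10,
               ) -> Iterator[tuple[CoordinateSet, CoordinateSet]]:
    """Stream of (base, noisy replica) structure pairs for validation runs.

    Bases are drawn with residue counts uniform over ``n_res_range``; each
    base yields ``pairs_per_base`` replicas whose noise scales cycle through
    ``noise_levels``, so the suite spans near-identical to highly divergent
    pairs.  Fully deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    produced = 0
    while produced < n_pairs:
        n_res = int(rng.integers(n_res_range[0], n_res_range[1] + 1))
        base = make_base_structure(n_res, int(rng.integers(0, 2**31 - 1)))
        for _ in range(min(pairs_per_base, n_pairs - produced)):
            sd = noise_levels[produced % len(noise_levels)]
            rep = perturb(base, sd, True, int(rng.integers(0, 2**31 - 1)))
            yield base, rep
            produced += 1


class DegeneratePair(NamedTuple):
    name: str
    a: CoordinateSet
    b: CoordinateSet
    expected_rmsd: float | None   # None: finite, no NaN, but value not pinned


def degenerate_fixtures() -> list[DegeneratePair]:
    """Labelled adversarial pairs for the precision-sensitive edge cases."""
    rng = np.random.default_rng(987654321)
    cloud = rng.uniform(-8.0, 8.0, size=(30, 3))
    A = CoordinateSet(cloud, "cloud")
    Rz = quaternion_to_rotation(np.array([np.cos(0.7), 0.0, 0.0, np.sin(0.7)]))

    out = [
        DegeneratePair("identical", A, CoordinateSet(cloud.copy(), "cloud-copy"), 0.0),
        DegeneratePair("translated", A,
                       CoordinateSet(cloud + np.array([11.0, -7.0, 23.0]), "cloud-t"), 0.0),
        DegeneratePair("rotated", A,
                       CoordinateSet(cloud @ Rz.T + np.array([1.0, 2.0, 3.0]), "cloud-rt"), 0.0),
    ]

    # collinear sets with different spacings: finite RMSD, rank-1 covariance
    s1 = np.linspace(0.0, 40.0, 12)
    s2 = s1 + rng.uniform(-1.5, 1.5, size=12)
    line_a = np.zeros((12, 3))
    line_a[:, 0] = s1
    line_b = np.zeros((12, 3))
    line_b[:, 0] = s2
    line_b = line_b @ Rz.T + np.array([-4.0, 9.0, 2.0])
    out.append(DegeneratePair("collinear",
                              CoordinateSet(line_a, "line-a"),
                              CoordinateSet(line_b, "line-b"), None))

    # planar sets (z = 0), rank-2 covariance
    plane = rng.uniform(-10.0, 10.0, size=(16, 3))
    plane[:, 2] = 0.0
    plane_b = plane.copy()
    plane_b[:, :2] += rng.normal(0.0, 0.8, size=(16, 2))
    out.append(DegeneratePair("planar",
                              CoordinateSet(plane, "plane-a"),
                              CoordinateSet(plane_b @ Rz.T + 5.0, "plane-b"), None))

    # reflection of a planar set is reachable by a proper rotation: RMSD 0
    mirror = plane.copy()
    mirror[:, 0] *= -1.0
    out.append(DegeneratePair("planar_mirror",
                              CoordinateSet(plane, "plane-a"),
                              CoordinateSet(mirror, "plane-mirror"), 0.0))

    out.append(DegeneratePair(
        "near_identical", A,
        CoordinateSet(cloud + rng.normal(0.0, 1e-4, size=cloud.shape), "cloud-eps"),
        None))

    # coordinates near 1e4 A: stresses single-precision mean subtraction
    offset = np.array([1.0e4, 1.0e4, 1.0e4])
    big_a = cloud + offset
    big_b = (cloud + rng.normal(0.0, 0.5, size=cloud.shape)) @ Rz.T
    big_b = big_b + offset + np.array([3.0, -2.0, 1.0])
    out.append(DegeneratePair("large_offset",
                              CoordinateSet(big_a, "big-a"),
                              CoordinateSet(big_b, "big-b"), None))
    return out
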