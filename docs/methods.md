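# Methods

## Model and procedure

The quantity computed everywhere is the RMSD after optimal rigid
superposition of two ordered coordinate sets in 1:1 positional
correspondence. Correspondence is positional only (atom k against atom k);
weights are uniform; reflections are never admitted as superpositions.

The quaternion formulation avoids rotating any coordinates. One traversal
of the paired coordinates accumulates the nine raw products Σ a_k b_kᵀ, the
two coordinate sums, and the two squared norms; the barycenter terms are
subtracted afterwards, so the centered covariance R, and the centered norms
gA and gB, cost a single fetch of the coordinates. R determines the
symmetric traceless 4×4 key matrix F whose largest eigenvalue λ_max gives

    RMSD² = (gA + gB − 2 λ_max) / N .

The radicand is clamped at zero before the square root: for identical or
near-identical inputs rounding can push it a hair negative, and the clamp
is what keeps every precision mode NaN-free. The dominant eigenvector of F
is the optimal rotation as a unit quaternion (scalar-first); mapping it to
a rotation matrix and measuring the deviation explicitly reproduces the
eigenvalue route, which is used as an internal cross-check.

## Eigensolvers

* **Cyclic Jacobi (production).** Fixed raster pivot order (0,1), (0,2),
  (0,3), (1,2), (1,3), (2,3); the stable t = sign(θ)/(|θ|+sqrt(θ²+1))
  rotation parameterisation; a pivot is skipped when |F_pq| ≤ 1e-30·‖F‖ to
  guard the rotation angle against 0/0. Convergence is declared when
  off(F) = sqrt(Σ_{p<q} F_pq²) ≤ tol·‖F‖_F of the input matrix; tol
  defaults to 1e-12 in binary64 and 1e-7 in binary32, with a 50-sweep
  budget. Each rotation removes 2 F_pq² from off(F)², so the off-diagonal
  mass decays monotonically; in practice 4–7 sweeps suffice and the solver
  converges for every symmetric input in both widths (exercised on 10⁴
  random matrices per run). The batched kernel applies identity updates to
  already-converged matrices, making results bit-independent of batch
  composition.
* **Characteristic polynomial + Newton (comparison).** Quartic
  coefficients from the trace powers and determinant; iteration starts at
  the analytic upper bound λ₀ = (gA+gB)/2, which brackets the largest root
  from the right, and stops when |Δλ| ≤ tol·|λ₀| (tol 1e-12 in binary64,
  1e-6 in binary32; 50 iterations). Non-finite iterates or a vanishing
  derivative freeze the estimate and clear the convergence flag — in
  binary32 this solver is *expected* to misbehave occasionally, and the
  contract is that failure is flagged, never silently returned. Near a
  multiple root (rank-deficient covariance, e.g. collinear sets) Newton
  stalls at the usual sqrt(machine-epsilon) limit and honestly reports
  non-convergence even though the value is still accurate to ~1e-8·(gA+gB).
* **Shifted power iteration (comparison).** Shift σ = maximum absolute row
  sum (Gershgorin), making the algebraically largest eigenvalue dominant;
  Rayleigh-quotient estimate, deterministic asymmetric start vector,
  stopping when successive estimates differ by ≤ tol·(|estimate|+σ).
* **Rotational method (oracle).** Kabsch: SVD of the centered covariance
  with determinant sign correction, deviation evaluated explicitly on the
  superposed coordinates, always in binary64. For rank-deficient sets the
  minimiser is not unique; the RMSD is, and is what tests rely on.

## Precision policy

`double` runs everything in binary64. `single` computes every elementary
result in binary32 (genuine float32 arrays end to end). `mixed` — the
default — accumulates the covariance in binary64 and rounds the key-matrix
entries to binary32 before the (binary32) Jacobi solve. The point of the
compromise is visible in the large-coordinate-offset fixture: with
coordinates near 10⁴ Å, the mean-subtraction step cancels catastrophically
in binary32 (gA is garbage), while 64-bit accumulation leaves a small,
accurate centered problem to which binary32 eigensolving is harmless.

What mixed precision cannot do is resolve RMSD differences finer than the
binary32 representation of λ_max. F's entries are of order gA ≈ N·Rg²
(≈ 4·10⁵ Ų for a 140-residue all-atom-sized chain), so λ_max carries an
absolute uncertainty of about one ulp, ~0.03 Ų, independent of how similar
the structures are. Propagated through the RMSD formula this is
δRMSD ≈ ulp/(2·N·RMSD): negligible (~10⁻⁵ Å) for decoy-like divergence
≳ 0.5 Å, but ~10⁻³ Å for near-identical pairs (RMSD ≈ 0.02 Å), and
self-comparisons in mixed mode read ~10⁻³ Å rather than exactly zero
(clamped to zero when the rounding residue happens to be negative).
Consequently agreement with the binary64 reference to two rounded decimal
places holds throughout the divergent regime but *cannot* hold universally
over large suites that include near-identical pairs — some values land
within δRMSD of a rounding boundary. The acceptance script therefore
reports the largest decimal count at which agreement is exact for every
pair; with near-identical pairs included that is 1, with the 2-decimal
agreement recovered as soon as pairs below ~0.1 Å divergence are absent.
This is a representation floor, not an implementation artifact: rerunning
the binary64 Jacobi on the binary32-rounded key matrix shows the same
limit.

## Synthetic ensembles

Real decoy sets are emulated, not reproduced. A base "fold" is a
self-avoiding pseudo-chain: 8 pseudo-atoms per residue (approximating
small-protein all-atom counts), consecutive points exactly 3.8 Å apart,
non-consecutive points at least 3.0 Å apart. Candidate step directions are
drawn at random and rejected on clashes; the draw is biased toward a
space-filling serpentine guide path so the chain packs like a globule
(radius of gyration 15–20 Å for 70–140 residues) instead of an expanded
coil — an unguided walk at that density jams. The walk backtracks when
stuck and restarts from scratch at most 20 times before raising a
generation error. Decoys are the base plus isotropic per-coordinate
Gaussian noise (sd 0.01–10 Å spans near-duplicate to fully divergent) and
a random rigid motion (uniform random rotation, translation in ±50 Å).
Everything is bit-reproducible from (config, seed), with child seeds drawn
below 2³¹.

What the generator does *not* model: real backbone geometry and side-chain
chemistry, secondary structure, the correlated (non-isotropic) deviations
of physical decoys, and energy-based filtering of ensembles. Passing tests
therefore demonstrate numerical behaviour over realistic sizes, scales and
degeneracies — not biological realism of the conformations themselves.

The degenerate catalogue (identical / translated / rotated / collinear /
planar / mirrored-planar / near-identical / 10⁴ Å-offset pairs) is built on
small clouds of a few dozen atoms: these are edge-case probes for the
arithmetic, sized so their expected properties are exactly testable.

## Problem sizes and defaults

Validation runs use 1000 pairs (70–140 residues, four noise scales) for
cross-method agreement, 10⁴ random symmetric matrices for eigensolver
correctness, and one full M = 1000 ensemble (499,500 pairs, ~100 residues)
for the end-to-end matrix engine — sizes chosen to match the regime the
method targets while keeping a full validation run in minutes on one CPU.
Engine defaults: method `qj`, policy `mixed`, batch size 4096 (a
cache-chunking knob that provably does not affect results; the engine
recomputes any pair whose iterative backend failed to converge with the
rotational method and records it).

## Known limitations

* No sequence alignment or atom-name matching; inputs must already
  correspond.
* No weighted superposition, no outlier rejection, no mmCIF or trajectory
  formats.
* The similarity matrix is held in memory (M = 5000 → 12.5 M doubles,
  ~100 MB; fine at the scales targeted).
* Timing output of the benchmark harness is hardware bookkeeping only;
  only the cross-method discrepancies it reports are contractual.
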