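# Methods

## Model and conventions

A response problem consists of real half-space blocks: symmetric `A`, `B`
(Hessian) and `Sigma` (metric), antisymmetric `Delta` (metric), over
`N = n_orb + n_ci` parameters.  The full paired matrices are

    E[2] = [[A, B], [B, A]],     S[2] = [[Sigma, Delta], [-Delta, -Sigma]].

A problem is *stable* when `A+B` and `A-B` are positive definite; then all
generalized eigenvalues of `E[2] x = w S[2] x` are real and come in `+/- w`
pairs, and the positive branch (the excitation energies) carries positive
metric norm `x^T S[2] x > 0`.  Everything is real: imaginary perturbation
operators (magnetic dipole, velocity gauge) enter only through the imaginary
part of their property gradients, which are embedded as

    B_full = (gR + i*gI ; gR - i*gI),

i.e. the real part is gerade (symmetric across the pairing) and the
imaginary part ungerade.  The damped polarizability is

    alpha_AB(w) = A_full^dagger (E[2] - (w + i*gamma) S[2])^{-1} B_full ,

a sign convention chosen so that `Im alpha` is positive at resonance for
electric-dipole diagonal elements on stable problems.  Useful symmetries
(both tested): for real gradients `alpha(-w) = conj(alpha(w))` at fixed
`gamma` (Re even, Im odd), and alpha is exactly even under the joint flip
`(w, gamma) -> (-w, -gamma)`; these two statements are equivalent ways of
expressing conjugation symmetry, since alpha depends on `w` and `gamma`
only through `z = w + i*gamma` and is even in `z` for real gradients.

In the Tamm-Dancoff approximation the `B` and `Delta` blocks are dropped.
The excitation and de-excitation blocks then decouple but the de-excitation
(antiresonant) branch is *retained* in all property contractions:
`alpha_TDA = a^dagger (A - z Sigma)^{-1} g + a^T (A + z Sigma)^{-1} conj(g)`.
This keeps conjugation symmetry intact and makes a TDA run identical to an
RPA run on a problem whose `B` and `Delta` blocks vanish — an identity the
iterative engine realizes by simply dropping `B`/`Delta` from its products
while keeping the paired bookkeeping.  Interfaces take frequencies, damping
factors and spectral windows in eV (1 hartree = 27.211386 eV); all internal
algebra is in atomic units.

## The iterative engine

Trial vectors are half-space vectors tagged gerade/ungerade and
orbital/CI (exactly one block populated).  The Hessian preserves the pairing
symmetry (`sigma_g = (A+B) b_g`, `sigma_u = (A-B) b_u`) and the metric flips
it (`tau_g = (Sigma+Delta) b_g` is ungerade, `tau_u = (Sigma-Delta) b_u`
gerade).  Projection of the two coupled real equations onto gerade and
ungerade bases gives the four-coupled reduced system in
`(X_g^R, X_u^R, X_u^I, X_g^I)` documented in `solver.py`; gerade–ungerade
Hessian cross blocks and same-symmetry metric blocks vanish identically, and
`S_ug = S_gu^T`.  Reduced blocks grow incrementally — only rows/columns for
newly admitted vectors are computed, from cached sigma/tau products, and one
LU factorization per frequency serves all operator components.

Candidates are admitted by classical Gram–Schmidt performed twice within
their (symmetry, block) pool; cross-pool orthogonality holds by
construction.  A candidate survives if its remaining norm exceeds the
linear-dependence threshold (default 1e-8, the tighter 1e-10 is available).
Convergence of an equation is judged by the total residual norm — the
Euclidean norm over all four residual components in full space — *relative
to the norm of its gradient*.  The relative criterion makes the observed
law "threshold 10^-n gives ~2n correct digits" scale-invariant; synthetic
gradients have arbitrary norms, so an absolute criterion would tie accuracy
to problem size.  Both laws (quadratic property convergence, 2n digits) are
asserted by the acceptance tests.

The preconditioner is the exact inverse of the elementwise 4x4 model built
from `diag(A±B)` and `diag(Sigma)` at each `(w, gamma)`; nothing
frequency-dependent is stored.  Elements whose 4x4 determinant falls below
the regularization constant (default 1e-8) are shifted before inversion.
On a fully diagonal problem the model is the exact inverse, so the very
first iteration converges — a testable contract.  Initial guesses are the
preconditioned property gradients.  Each preconditioned residual is split
into orbital and CI candidates (up to eight per equation per iteration);
optionally CI candidates are projected orthogonal to a designated reference
direction (off by default — the synthetic problems have no distinguished
reference state, but multiconfigurational practice sometimes requires it).

### Subspace collapse

When a block (orbital or CI) exceeds its cap, the block's basis is replaced
by the left singular vectors of the current full-space solution estimates
restricted to that block and symmetry, screening singular values below
1e-10 (columns are normalized first).  The collapse happens *before* the
iteration's new trial vectors are admitted, so the restart basis is the
solution span plus fresh residual directions; collapsing after admission
would discard the new directions before they ever enter a solve and the
iteration stalls.  Sigma/tau caches for the new basis are recomputed (this
counts toward the Hessian-application tally — bounding memory costs
iterations and products, as the capped-run tests show).  If every singular
value is screened out, the largest direction is kept and a warning issued.
The post-collapse size is whatever rank the solutions require; the cap is a
trigger, not a hard ceiling, so a cap far below the solution rank causes a
collapse every iteration (correct but wasteful).

### Dynamic frequency scheduling

With dynamic scheduling enabled, only `dynamic_initial_count` evenly spaced
grid points start active (default 4).  When the worst residual among active
unconverged equations drops below the add threshold (default 1e-2), the
immediate grid neighbors of the active set are activated; they are first
solved in the existing subspace — often converging immediately — before any
expansion on their behalf.  All frequencies are eventually activated, and
the final spectra agree with static solves to well below the convergence
tolerance while strictly fewer Hessian applications are accumulated (the
tested proxy for wall-clock savings; timings themselves are not asserted).

## Properties and decomposition

Cross-sections use `sigma_abs = (4 pi w / c) * Im tr(alpha)/3` in atomic
units (`c = 137.035999`); the printed constant is conventional — any fixed
prefactor preserves every equivalence test — and outputs are labeled
arbitrary units.  The isotropic average is `tr/3`.  The mixed tensor `G'`
is the plain contraction of electric gradients with the magnetic-dipole
response (unit factor 1, documented), so labeling the electric gradient as
magnetic reproduces alpha exactly.

The decomposition attributes the elementwise products
`Im(conj(A_n) X_n)` to orbital pairs `(p, q)`: exactly for the orbital
block via the pair map, approximately for the CI block via squared
transition-density weights `T[pq, i]^2`.  A complete (column-orthonormal)
map has unit column norms and leaves zero unmapped residual; a truncated
map leaves a positive one.  Cartesian components are summed into one
partial spectrum per pair, and conservation — partial spectra plus
unmapped residual equal `sigma_abs` at every frequency — is exact by
construction and asserted to 1e-10.  Post-broadening convolves the curves
with a normalized discrete Gaussian of given HWHM (Voigt-like profiles on
top of the Lorentzian damping), preserving interior area.

## Synthetic generator

The generator emulates the *structure* a converged multiconfigurational
reference provides, not its physics: diagonal energies drawn uniformly
inside the requested window (default 5–15 eV), random symmetric/antisymmetric
couplings at a perturbative scale set by `coupling_scale` (default 1.0;
0 gives the decoupled diagonal limit), `Sigma` floored to be comfortably
positive definite, and stability repaired by shifting `A` so that
`eig(A±B) >= stability_margin` (default 0.5 eV).  After repair the dense
eigen-oracle verifies every excitation energy lies inside the window; if a
pass fails, couplings are reduced and the loop retried, and a problem that
cannot be repaired raises rather than returning an unstable container.
Gradients are dense standard-normal vectors; the CI transition map is
column-orthonormal by construction (complete when `n_ci <= n_orb`), with a
deliberate rank-truncation option.  Equal seeds give bit-identical
problems.

What the generator does *not* emulate: sparsity and locality of real
Hessians, the huge dimension gap between orbital and CI spaces, realistic
transition-moment distributions, or point-group symmetry.  Consequently the
subspace saturates quickly on small problems (a batch of many frequencies
can converge in one iteration once the candidate count reaches the space
dimension), and tests of iteration *behavior* (collapse, dynamic
scheduling, shared-subspace benefit) deliberately use larger problems
(N = 300) with scan windows much narrower than the spectral range, where
the subspace stays well below saturation.  Passing tests demonstrate the
algebra and the algorithmic contracts at desk scale — a few hundred
parameters, dense linear algebra throughout — not performance at molecular
scale.

## Known limitations

- Dense `N x N` blocks only; no matrix-free Hessian interface.
- No distributed-memory parallelism; all tests target a single CPU.
- The ECD/ORD and cross-section prefactors are conventional constants, not
  calibrated to experimental units.
- The collapse cap is a trigger rather than a hard memory ceiling (see
  above).
- TDA runs reuse the paired four-coupled machinery (two of the four
  residual components are redundant there), trading a factor ~2 of reduced
  work for a single code path.
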