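"""Exact dense reference solvers.

These oracles solve the damped response equation by direct inversion, solve
the paired generalized eigenproblem densely, and assemble the sum-over-states
(Lorentzian) spectrum.  They exist to verify the iterative subspace engine:
with a complete set of roots the sum-over-states spectrum is identical to
direct inversion, and a converged iterative run must agree with both.

Conventions
-----------
The polarizability is the contraction

    alpha_AB(w) = A_full^dagger (E2 - (w + i*gamma) S2)^{-1} B_full

with the gradient embedding of :class:`cpprop.problems.OperatorGradient`.
This sign makes Im(alpha) positive at resonance for electric-dipole diagonal
elements on stable problems.  In the TDA both the resonant (excitation) and
antiresonant (de-excitation) branches are retained, so the TDA spectrum
equals the RPA spectrum of a problem with vanishing B and Delta blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import scipy.linalg as sla

from .errors import SingularityError
from .problems import OperatorGradient, ResponseProblem, assemble_dense
from .units import ev_to_au

__all__ = [
    "EigenResult",
    "direct_inversion_solve",
    "direct_inversion_alpha",
    "generalized_eigensolve",
    "sum_over_states_alpha",
]


@dataclass
class EigenResult:
    """Dense eigen solution: excitation energies, vectors and moments.

    ``energies`` are the positive excitation energies in eV, ascending.
    ``vectors`` holds the metric-normalized right eigenvectors as columns
    (full 2N space for RPA, N space for TDA).  ``moments[(op, comp)][n]`` is
    the transition moment  x_n . g  of state n with the (complex) gradient g.
    """

    energies: np.ndarray
    vectors: np.ndarray
    moments: dict = field(default_factory=dict)
    tda: bool = False
    complete: bool = True

    @property
    def n_states(self) -> int:
        return self.energies.size


def _gradient_full(problem: ResponseProblem, gradient: OperatorGradient, tda: bool):
    if tda:
        return gradient.real_part + 1j * gradient.imag_part
    return gradient.full()


def direct_inversion_solve(
    problem: ResponseProblem,
    omega: float,
    gamma: float,
    gradient_B: OperatorGradient,
    tda: bool = False,
) -> np.ndarray:
    """Solve (E2 - (w + i*gamma) S2) X = B by dense direct inversion.

    ``omega`` and ``gamma`` are in eV.  For the TDA only the resonant
    (excitation-block) solution is returned (dimension N); for RPA the full
    2N paired solution.  At gamma = 0 an exact pole raises
    :class:`SingularityError`.
    """
    E2, S2 = assemble_dense(problem, tda=tda)
    z = ev_to_au(omega) + 1j * ev_to_au(gamma)
    M = E2 - z * S2
    rhs = _gradient_full(problem, gradient_B, tda)
    try:
        X = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularityError(f"singular damped equation at omega={omega} eV") from exc
    resid = np.linalg.norm(M @ X - rhs)
    if resid > 1e-8 * max(np.linalg.norm(rhs), 1e-300):
        raise SingularityError(
            f"damped equation numerically singular at omega={omega} eV "
            f"(relative residual {resid / np.linalg.norm(rhs):.2e})"
        )
    return X


def direct_inversion_alpha(
    problem: ResponseProblem,
    omegas: np.ndarray,
    gamma: float,
    a_operators: list[OperatorGradient],
    b_operators: list[OperatorGradient],
    tda: bool = False,
) -> np.ndarray:
    """Complex polarizability tensor alpha[w, i, j] by dense inversion.

    Rows follow ``a_operators``, columns ``b_operators``; frequencies in eV.
    In the TDA the antiresonant branch (A + z*Sigma) is solved as well so the
    contraction carries both resonant and antiresonant terms.
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    na, nb = len(a_operators), len(b_operators)
    alpha = np.empty((omegas.size, na, nb), dtype=complex)
    E2, S2 = assemble_dense(problem, tda=tda)
    gamma_au = ev_to_au(gamma)
    for iw, w in enumerate(omegas):
        z = ev_to_au(w) + 1j * gamma_au
        if tda:
            Mp = E2 - z * S2
            Mm = E2 + z * S2
            for j, gb in enumerate(b_operators):
                g = gb.real_part + 1j * gb.imag_part
                xp = np.linalg.solve(Mp, g)
                xm = np.linalg.solve(Mm, np.conj(g))
                for i, ga in enumerate(a_operators):
                    a = ga.real_part + 1j * ga.imag_part
                    alpha[iw, i, j] = np.conj(a) @ xp + a @ xm
        else:
            M = E2 - z * S2
            for j, gb in enumerate(b_operators):
                X = np.linalg.solve(M, gb.full())
                for i, ga in enumerate(a_operators):
                    alpha[iw, i, j] = np.conj(ga.full()) @ X
    return alpha


def generalized_eigensolve(
    problem: ResponseProblem,
    tda: bool = False,
    n_roots: int | None = None,
) -> EigenResult:
    """Dense generalized eigensolve of the paired pencil E2 x = w S2 x.

    Returns the ``n_roots`` lowest positive excitation energies with
    metric-normalized vectors (x^T S2 x = +1) and per-gradient transition
    moments.  Degenerate clusters are orthonormalized in the S2 metric and
    each vector's first significant component is fixed positive so strengths
    are reproducible.
    """
    E2, S2 = assemble_dense(problem, tda=tda)
    N = E2.shape[0]
    max_roots = N if tda else N // 2
    if n_roots is None:
        n_roots = max_roots
    if n_roots > max_roots:
        warnings.warn(f"n_roots={n_roots} exceeds available {max_roots}; capped")
        n_roots = max_roots

    if tda:
        w, V = sla.eigh(E2, S2)
        order = np.argsort(w)
        w, V = w[order], V[:, order]  # eigh already Sigma-orthonormalizes
    else:
        w, V = sla.eig(E2, S2)
        if np.max(np.abs(w.imag)) > 1e-8 * max(1.0, np.max(np.abs(w.real))):
            raise ValueError("complex eigenvalues: problem is not stable")
        w = w.real
        V = V.real if np.max(np.abs(V.imag)) < 1e-8 else V
        pos = w > 0
        w, V = w[pos], V[:, pos]
        order = np.argsort(w, kind="stable")
        w, V = w[order], V[:, order]
        # S2-orthonormalize within near-degenerate clusters, then normalize
        # to x^T S2 x = +1 (positive-norm selection for excitation roots).
        i = 0
        while i < w.size:
            j = i + 1
            while j < w.size and (w[j] - w[i]) < 1e-10 * max(1.0, w[i]):
                j += 1
            for k in range(i, j):
                x = V[:, k]
                for m in range(i, k):
                    x = x - V[:, m] * (V[:, m] @ (S2 @ x))
                V[:, k] = x
            i = j
        norms = np.einsum("in,ij,jn->n", V, S2, V)
        if np.any(norms <= 0):
            raise ValueError("non-positive metric norm on an excitation root")
        V = V / np.sqrt(norms)

    w, V = w[:n_roots], V[:, :n_roots]
    # Deterministic sign: first component with magnitude > 1e-8 made positive.
    for k in range(w.size):
        nz = np.nonzero(np.abs(V[:, k]) > 1e-8)[0]
        if nz.size and V[nz[0], k] < 0:
            V[:, k] = -V[:, k]

    moments = {}
    for g in problem.gradients:
        gf = _gradient_full(problem, g, tda)
        moments[(g.operator_id, g.component)] = V.T @ gf

    from .units import au_to_ev
    return EigenResult(energies=au_to_ev(w), vectors=V, moments=moments,
                       tda=tda, complete=(n_roots == max_roots))


def sum_over_states_alpha(
    eigen: EigenResult,
    a_keys: list[tuple[str, str]],
    b_keys: list[tuple[str, str]],
    omegas: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Sum-over-states polarizability tensor on a frequency grid (eV in, a.u. out).

    alpha_AB(w) = sum_n [ conj(f^A_n) f^B_n / (w_n - z) + f^A_n conj(f^B_n) / (w_n + z) ]

    with z = w + i*gamma and f^G_n the transition moment of state n with
    gradient G.  Requires all positive roots for exact agreement with direct
    inversion; with an incomplete root set the result is flagged approximate
    by the caller via ``eigen.complete``.
    """
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    if not eigen.complete:
        warnings.warn("incomplete root set: sum-over-states spectrum is approximate")
    wn = ev_to_au(eigen.energies)
    z = ev_to_au(omegas) + 1j * ev_to_au(gamma)
    alpha = np.zeros((omegas.size, len(a_keys), len(b_keys)), dtype=complex)
    res = 1.0 / (wn[None, :] - z[:, None])     # (nw, nstates)
    anti = 1.0 / (wn[None, :] + z[:, None])
    for i, ka in enumerate(a_keys):
        fa = eigen.moments[ka]
        for j, kb in enumerate(b_keys):
            fb = eigen.moments[kb]
            alpha[:, i, j] = res @ (np.conj(fa) * fb) + anti @ (fa * np.conj(fb))
    return alpha
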