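"""Iterative damped-response engine: paired gerade/ungerade real-algebra
subspace solver with diagonal preconditioning, CI/orbital trial-vector split,
SVD subspace collapse, and dynamic frequency scheduling.

Real algebra
------------
Writing the damped equation (E2 - (w + i*gamma) S2) X = B with X = XR + i XI
and B = BR + i BI gives two coupled real equations.  Every real full-space
vector (v1; v2) decomposes into a gerade part (z; z), z = (v1+v2)/2, and an
ungerade part (z; -z), z = (v1-v2)/2.  The Hessian preserves this symmetry
(sigma_g = (A+B) b_g, sigma_u = (A-B) b_u) while the metric flips it
(tau_g = (Sigma+Delta) b_g is ungerade, tau_u = (Sigma-Delta) b_u is gerade).
Under the gradient embedding used here BR is purely gerade and BI purely
ungerade, and projection onto a subspace of gerade half-vectors V_g and
ungerade half-vectors V_u yields four coupled reduced equations in the
unknown coefficient vectors (c_gR, c_uR, c_uI, c_gI):

    [ E_gg    -w S_gu   g S_gu    0     ] [c_gR]   [V_g^T gR]
    [ -w S_ug  E_uu     0         g S_ug] [c_uR] = [   0    ]
    [ -g S_ug  0        E_uu     -w S_ug] [c_uI]   [V_u^T gI]
    [ 0       -g S_gu  -w S_gu    E_gg  ] [c_gI]   [   0    ]

with E_gg[i,j] = b_g_i . sigma_g_j, E_uu likewise, S_gu[i,j] = b_g_i . tau_u_j
and S_ug = S_gu^T.  Gerade-ungerade Hessian cross blocks and same-symmetry
metric blocks vanish identically.  In the TDA the B and Delta blocks are
dropped from the sigma/tau products; the paired machinery is otherwise
unchanged (excitation and de-excitation blocks decouple).

Convergence is monitored by the total residual norm -- the Euclidean norm of
all four full-space residual components -- relative to the norm of the
full-space gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .problems import (ELECTRIC_DIPOLE, OperatorGradient, ResponseProblem,
                       SolverOptions)
from .units import ev_to_au

logger = logging.getLogger(__name__)

__all__ = [
    "PairedVector", "TrialSubspace", "ReducedSystem", "Preconditioner",
    "EquationState", "ResponseSolution",
    "split_gerade_ungerade", "apply_hessian_metric", "extend_subspace",
    "assemble_reduced", "solve_reduced", "back_project_and_residuals",
    "precondition", "collapse_subspace", "schedule_frequencies", "run_cpp",
]

GERADE = "gerade"
UNGERADE = "ungerade"
ORBITAL = "orbital"
CI = "ci"


@dataclass(eq=False)
class PairedVector:
    """Half-space trial vector tagged by pairing symmetry and parameter block."""

    half: np.ndarray
    symmetry: str  # gerade | ungerade
    block: str     # orbital | ci

    def __post_init__(self):
        if self.symmetry not in (GERADE, UNGERADE):
            raise ValueError(f"bad symmetry tag {self.symmetry!r}")
        if self.block not in (ORBITAL, CI):
            raise ValueError(f"bad block tag {self.block!r}")
        self.half = np.asarray(self.half, dtype=float)

    def norm(self) -> float:
        return float(np.linalg.norm(self.half))


def split_gerade_ungerade(full_vector: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a full pair-space vector into (gerade, ungerade) half vectors.

    gerade = (upper + lower)/2, ungerade = (upper - lower)/2; the full vector
    is exactly (g + u ; g - u).
    """
    v = np.asarray(full_vector)
    if v.ndim != 1 or v.size % 2:
        raise ValueError("full vector must be 1-D with even length")
    n = v.size // 2
    return 0.5 * (v[:n] + v[n:]), 0.5 * (v[:n] - v[n:])


def _effective_matrices(problem: ResponseProblem, tda: bool):
    """(Ap, Am, Sp, Sm): Hessian/metric half-space products per symmetry."""
    A, B = problem.A_block, problem.B_block
    S, D = problem.Sigma_block, problem.Delta_block
    if tda:
        return A, A, S, S
    return A + B, A - B, S + D, S - D


def apply_hessian_metric(problem: ResponseProblem, v: PairedVector,
                         tda: bool = False) -> tuple[PairedVector, PairedVector]:
    """Hessian and metric products of one trial vector.

    sigma keeps the symmetry tag of ``v``; tau carries the opposite tag
    (the metric flips gerade/ungerade).
    """
    Ap, Am, Sp, Sm = _effective_matrices(problem, tda)
    other = UNGERADE if v.symmetry == GERADE else GERADE
    if v.symmetry == GERADE:
        sigma, tau = Ap @ v.half, Sp @ v.half
    else:
        sigma, tau = Am @ v.half, Sm @ v.half
    return (PairedVector(sigma, v.symmetry, v.block),
            PairedVector(tau, other, v.block))


@dataclass
class ReducedSystem:
    """Reduced-subspace blocks; S_ug is the transpose of S_gu by symmetry."""

    E_gg: np.ndarray
    E_uu: np.ndarray
    S_gu: np.ndarray

    @property
    def S_ug(self) -> np.ndarray:
        return self.S_gu.T


class TrialSubspace:
    """Orthonormal paired trial basis with cached sigma/tau projections.

    Vectors live in four pools keyed by (symmetry, block).  Orthogonalization
    is performed within a pool (cross-pool orthogonality holds by construction:
    gerade/ungerade full vectors are orthogonal, and orbital/CI half vectors
    have disjoint support).  The reduced Gram blocks are grown incrementally
    as vectors are admitted; no Hessian application is ever repeated.
    """

    def __init__(self, problem: ResponseProblem, tda: bool = False,
                 lindep_threshold: float = 1e-8):
        self.problem = problem
        self.tda = tda
        self.lindep_threshold = lindep_threshold
        N = problem.half_dim
        self._N = N
        # Per symmetry: basis rows, sigma rows, tau rows (all half space).
        self.basis = {GERADE: np.empty((0, N)), UNGERADE: np.empty((0, N))}
        self.sigma = {GERADE: np.empty((0, N)), UNGERADE: np.empty((0, N))}
        self.tau = {GERADE: np.empty((0, N)), UNGERADE: np.empty((0, N))}
        self.blocks = {GERADE: [], UNGERADE: []}  # block tag per vector
        self.E = {GERADE: np.empty((0, 0)), UNGERADE: np.empty((0, 0))}
        self.S_gu = np.empty((0, 0))
        self.sigma_build_count = 0
        self._grad_proj: dict = {}  # (op, comp) -> {"gR": arr n_g, "gI": arr n_u, "grad": OperatorGradient}

    # -- sizes ----------------------------------------------------------
    def n(self, symmetry: str) -> int:
        return self.basis[symmetry].shape[0]

    def n_block(self, block: str) -> int:
        return sum(b == block for b in self.blocks[GERADE] + self.blocks[UNGERADE])

    @property
    def size(self) -> int:
        return self.n(GERADE) + self.n(UNGERADE)

    def pool_sizes(self) -> dict:
        out = {}
        for sym in (GERADE, UNGERADE):
            for blk in (ORBITAL, CI):
                out[(sym, blk)] = sum(b == blk for b in self.blocks[sym])
        return out

    # -- gradients ------------------------------------------------------
    def register_gradient(self, grad: OperatorGradient) -> None:
        key = (grad.operator_id, grad.component)
        if key not in self._grad_proj:
            self._grad_proj[key] = {
                "grad": grad,
                "gR": self.basis[GERADE] @ grad.real_part,
                "gI": self.basis[UNGERADE] @ grad.imag_part,
            }

    def gradient_rhs(self, grad: OperatorGradient) -> tuple[np.ndarray, np.ndarray]:
        """Reduced right-hand-side projections (V_g^T gR, V_u^T gI)."""
        self.register_gradient(grad)
        p = self._grad_proj[(grad.operator_id, grad.component)]
        return p["gR"], p["gI"]

    # -- admission ------------------------------------------------------
    def _admit(self, v: PairedVector) -> None:
        sym = v.symmetry
        sigma, tau = apply_hessian_metric(self.problem, v, self.tda)
        self.sigma_build_count += 1
        b = v.half
        # Incremental Gram rows: E_sym gets one new symmetric row/column;
        # S_gu gets a row (gerade vector, via its own tau: b_g.tau_u_j =
        # tau_g_i.b_u_j) or a column (ungerade vector).
        nold = self.n(sym)
        row_E = self.sigma[sym] @ b if nold else np.empty(0)
        diag = float(b @ sigma.half)
        E_old = self.E[sym]
        E_new = np.empty((nold + 1, nold + 1))
        E_new[:nold, :nold] = E_old
        E_new[nold, :nold] = row_E
        E_new[:nold, nold] = row_E
        E_new[nold, nold] = diag
        self.E[sym] = E_new

        if sym == GERADE:
            new_row = self.basis[UNGERADE] @ tau.half  # tau_g . b_u_j
            self.S_gu = np.vstack([self.S_gu, new_row[None, :]])
        else:
            new_col = self.basis[GERADE] @ tau.half  # b_g_i . tau_u
            self.S_gu = np.hstack([self.S_gu, new_col[:, None]])

        self.basis[sym] = np.vstack([self.basis[sym], b[None, :]])
        self.sigma[sym] = np.vstack([self.sigma[sym], sigma.half[None, :]])
        self.tau[sym] = np.vstack([self.tau[sym], tau.half[None, :]])
        self.blocks[sym].append(v.block)

        for p in self._grad_proj.values():
            g = p["grad"]
            if sym == GERADE:
                p["gR"] = np.append(p["gR"], b @ g.real_part)
            else:
                p["gI"] = np.append(p["gI"], b @ g.imag_part)

    def extend(self, candidates: list[PairedVector]) -> int:
        """Gram-Schmidt (twice) and admit candidates above the linear-dependence
        threshold; returns the number admitted."""
        added = 0
        for v in candidates:
            nrm = v.norm()
            if not np.isfinite(nrm):
                raise ValueError("non-finite candidate trial vector")
            if nrm < 1e-300:
                logger.debug("zero candidate vector skipped")
                continue
            b = v.half / nrm
            pool_rows = [i for i, blk in enumerate(self.blocks[v.symmetry]) if blk == v.block]
            P = self.basis[v.symmetry][pool_rows]
            for _ in range(2):  # classical GS with reorthogonalization
                if P.shape[0]:
                    b = b - P.T @ (P @ b)
            rem = np.linalg.norm(b)
            if rem <= self.lindep_threshold:
                continue
            self._admit(PairedVector(b / rem, v.symmetry, v.block))
            added += 1
        return added

    # -- reduced system -------------------------------------------------
    def reduced(self) -> ReducedSystem:
        return ReducedSystem(E_gg=self.E[GERADE], E_uu=self.E[UNGERADE], S_gu=self.S_gu)

    def reduced_from_scratch(self) -> ReducedSystem:
        """Rebuild the reduced blocks directly from the caches (test oracle
        for the incremental bookkeeping)."""
        E_gg = self.basis[GERADE] @ self.sigma[GERADE].T
        E_uu = self.basis[UNGERADE] @ self.sigma[UNGERADE].T
        S_gu = self.basis[GERADE] @ self.tau[UNGERADE].T
        return ReducedSystem(E_gg=0.5 * (E_gg + E_gg.T), E_uu=0.5 * (E_uu + E_uu.T),
                             S_gu=S_gu)


def extend_subspace(subspace: TrialSubspace, candidates: list[PairedVector]) -> int:
    """Functional alias for :meth:`TrialSubspace.extend`."""
    return subspace.extend(candidates)


def assemble_reduced(subspace: TrialSubspace, omega_au: float, gamma_au: float):
    """Dense four-coupled reduced matrix at (omega, gamma), from cached blocks.

    Unknown ordering: (c_gR, c_uR, c_uI, c_gI).
    """
    r = subspace.reduced()
    ng, nu = r.E_gg.shape[0], r.E_uu.shape[0]
    n = 2 * (ng + nu)
    M = np.zeros((n, n))
    sl_gR = slice(0, ng)
    sl_uR = slice(ng, ng + nu)
    sl_uI = slice(ng + nu, ng + 2 * nu)
    sl_gI = slice(ng + 2 * nu, n)
    M[sl_gR, sl_gR] = r.E_gg
    M[sl_uR, sl_uR] = r.E_uu
    M[sl_uI, sl_uI] = r.E_uu
    M[sl_gI, sl_gI] = r.E_gg
    M[sl_gR, sl_uR] = -omega_au * r.S_gu
    M[sl_uR, sl_gR] = -omega_au * r.S_ug
    M[sl_uI, sl_gI] = -omega_au * r.S_ug
    M[sl_gI, sl_uI] = -omega_au * r.S_gu
    M[sl_gR, sl_uI] = gamma_au * r.S_gu
    M[sl_uR, sl_gI] = gamma_au * r.S_ug
    M[sl_uI, sl_gR] = -gamma_au * r.S_ug
    M[sl_gI, sl_uR] = -gamma_au * r.S_gu
    return M, (sl_gR, sl_uR, sl_uI, sl_gI)


def solve_reduced(M: np.ndarray, rhs: np.ndarray,
                  regularization: float = 1e-8) -> np.ndarray:
    """Solve the reduced four-coupled system; regularize if ill-conditioned."""
    if M.shape[0] == 0:
        return np.empty_like(rhs)
    try:
        c = np.linalg.solve(M, rhs)
        resid = np.linalg.norm(M @ c - rhs, axis=0)
        scale = np.linalg.norm(rhs, axis=0)
        if np.all(resid <= 1e-10 * np.maximum(scale, 1e-300)):
            return c
    except np.linalg.LinAlgError:
        pass
    logger.warning("ill-conditioned reduced system: solving with Tikhonov "
                   "regularization %.1e", regularization)
    n = M.shape[0]
    c = np.linalg.solve(M.T @ M + regularization * np.eye(n), M.T @ rhs)
    return c


@dataclass
class Preconditioner:
    """Diagonal model of the four-coupled system, inverted exactly per element.

    ``eg``/``eu`` are the diagonals of the gerade/ungerade Hessian combinations
    (A+B, A-B; plain A in the TDA) and ``s`` the diagonal of Sigma (Delta has a
    zero diagonal).  Nothing frequency-dependent is stored: the per-element
    4x4 model is assembled on the fly at each (omega, gamma).
    """

    eg: np.ndarray
    eu: np.ndarray
    s: np.ndarray
    regularization: float = 1e-8

    @classmethod
    def from_problem(cls, problem: ResponseProblem, tda: bool = False,
                     regularization: float = 1e-8) -> "Preconditioner":
        Ap, Am, Sp, _ = _effective_matrices(problem, tda)
        return cls(eg=np.diagonal(Ap).copy(), eu=np.diagonal(Am).copy(),
                   s=np.diagonal(Sp).copy(), regularization=regularization)

    def apply(self, r_gR, r_uR, r_uI, r_gI, omega_au: float, gamma_au: float):
        """Exactly invert the elementwise 4x4 diagonal model against the four
        residual components; returns four half vectors (gR, uR, uI, gI)."""
        N = self.eg.size
        M = np.zeros((N, 4, 4))
        M[:, 0, 0] = self.eg
        M[:, 1, 1] = self.eu
        M[:, 2, 2] = self.eu
        M[:, 3, 3] = self.eg
        M[:, 0, 1] = M[:, 1, 0] = M[:, 2, 3] = M[:, 3, 2] = -omega_au * self.s
        M[:, 0, 2] = M[:, 1, 3] = gamma_au * self.s
        M[:, 2, 0] = M[:, 3, 1] = -gamma_au * self.s
        dets = np.abs(np.linalg.det(M))
        bad = dets < self.regularization
        if np.any(bad):
            M[bad] += self.regularization * np.eye(4)
        rhs = np.stack([r_gR, r_uR, r_uI, r_gI], axis=1)
        x = np.linalg.solve(M, rhs[..., None])[..., 0]
        return x[:, 0], x[:, 1], x[:, 2], x[:, 3]


@dataclass
class EquationState:
    """One damped linear response equation: fixed (operator, component, omega)."""

    operator_id: str
    component: str
    omega_ev: float
    omega_index: int
    gradient: OperatorGradient
    active: bool = True
    converged: bool = False
    coeffs: tuple = None          # (c_gR, c_uR, c_uI, c_gI) reduced coefficients
    residual_history: list = field(default_factory=list)
    alpha_history: list = field(default_factory=list)  # complex vec over A components
    residual_norm: float = math.inf

    @property
    def key(self):
        return (self.operator_id, self.component, self.omega_index)


@dataclass
class ResponseSolution:
    """Converged (or flagged partial) solutions of a batch of response equations."""

    problem: ResponseProblem
    options: SolverOptions
    omegas_ev: np.ndarray
    equations: dict                # key -> EquationState
    solutions: dict                # key -> (X_gR, X_uR, X_uI, X_gI) full half vectors
    a_operators: list
    b_operators: list
    n_iterations: int = 0
    sigma_build_count: int = 0
    converged: bool = False
    iteration_table: list = field(default_factory=list)

    def solution_halves(self, operator_id: str, component: str, omega_index: int):
        return self.solutions[(operator_id, component, omega_index)]

    def full_complex_solution(self, operator_id: str, component: str,
                              omega_index: int) -> np.ndarray:
        """Reassemble the complex 2N-dimensional solution vector."""
        X_gR, X_uR, X_uI, X_gI = self.solution_halves(operator_id, component, omega_index)
        upper = (X_gR + X_uR) + 1j * (X_gI + X_uI)
        lower = (X_gR - X_uR) + 1j * (X_gI - X_uI)
        return np.concatenate([upper, lower])


def back_project_and_residuals(subspace: TrialSubspace, coeffs, gradient: OperatorGradient,
                               omega_au: float, gamma_au: float):
    """Full-space solution halves, the four residual half-vectors and the
    total residual norm, using only cached sigma/tau projections."""
    c_gR, c_uR, c_uI, c_gI = coeffs
    Bg, Bu = subspace.basis[GERADE], subspace.basis[UNGERADE]
    Sg, Su = subspace.sigma[GERADE], subspace.sigma[UNGERADE]
    Tg, Tu = subspace.tau[GERADE], subspace.tau[UNGERADE]
    gR, gI = gradient.real_part, gradient.imag_part

    X = (Bg.T @ c_gR, Bu.T @ c_uR, Bu.T @ c_uI, Bg.T @ c_gI)

    r_gR = gR - Sg.T @ c_gR + omega_au * (Tu.T @ c_uR) - gamma_au * (Tu.T @ c_uI)
    r_uR = -Su.T @ c_uR + omega_au * (Tg.T @ c_gR) - gamma_au * (Tg.T @ c_gI)
    r_uI = gI - Su.T @ c_uI + omega_au * (Tg.T @ c_gI) + gamma_au * (Tg.T @ c_gR)
    r_gI = -Sg.T @ c_gI + omega_au * (Tu.T @ c_uI) + gamma_au * (Tu.T @ c_uR)

    total = math.sqrt(2.0 * (r_gR @ r_gR + r_uR @ r_uR + r_uI @ r_uI + r_gI @ r_gI))
    return X, (r_gR, r_uR, r_uI, r_gI), total


def precondition(residuals, preconditioner: Preconditioner, omega_au: float,
                 gamma_au: float, problem: ResponseProblem,
                 ci_reference: np.ndarray | None = None) -> list[PairedVector]:
    """Turn the four residual components into up to eight block-pure trial
    vector candidates via the elementwise 4x4 diagonal-model inverse."""
    b_gR, b_uR, b_uI, b_gI = preconditioner.apply(*residuals, omega_au, gamma_au)
    out = []
    so, sc = problem.orbital_slice(), problem.ci_slice()
    for half, sym in ((b_gR, GERADE), (b_uR, UNGERADE), (b_uI, UNGERADE), (b_gI, GERADE)):
        for sl, blk in ((so, ORBITAL), (sc, CI)):
            v = np.zeros(problem.half_dim)
            v[sl] = half[sl]
            if blk == CI and ci_reference is not None and problem.n_ci:
                ref = ci_reference / np.linalg.norm(ci_reference)
                v[sc] = v[sc] - ref * (ref @ v[sc])
            if np.linalg.norm(v) > 0:
                out.append(PairedVector(v, sym, blk))
    return out


def collapse_subspace(subspace: TrialSubspace, solution_halves: list,
                      which_block: str, svd_threshold: float = 1e-10) -> TrialSubspace:
    """Collapse one parameter block of the subspace onto the dominant left
    singular vectors of the current solution estimates.

    ``solution_halves`` is a list of (X_gR, X_uR, X_uI, X_gI) tuples (one per
    active equation).  Only the requested block's pools are replaced; the
    other block and all caches for it are kept.  Returns a new subspace (the
    sigma/tau caches for the new basis are recomputed, which counts toward
    ``sigma_build_count``).
    """
    problem = subspace.problem
    sl = problem.orbital_slice() if which_block == ORBITAL else problem.ci_slice()
    keep_block = CI if which_block == ORBITAL else ORBITAL

    new = TrialSubspace(problem, tda=subspace.tda,
                        lindep_threshold=subspace.lindep_threshold)
    new.sigma_build_count = subspace.sigma_build_count

    def svd_basis(cols):
        if not cols:
            return []
        Mat = np.stack(cols, axis=1)
        norms = np.linalg.norm(Mat, axis=0)
        good = norms > 1e-300
        if not np.any(good):
            return []
        Mat = Mat[:, good] / norms[good]
        U, s, _ = np.linalg.svd(Mat, full_matrices=False)
        keep = s > svd_threshold
        if not np.any(keep):
            logger.warning("all singular values below threshold in %s collapse; "
                           "keeping the largest direction", which_block)
            keep = np.zeros_like(s, dtype=bool)
            keep[0] = True
        return [U[:, i] for i in range(s.size) if keep[i]]

    for sym in (GERADE, UNGERADE):
        comps = {GERADE: (0, 3), UNGERADE: (1, 2)}[sym]
        cols = []
        for halves in solution_halves:
            for c in comps:
                v = np.zeros(problem.half_dim)
                v[sl] = halves[c][sl]
                cols.append(v)
        for u in svd_basis(cols):
            new.extend([PairedVector(u, sym, which_block)])
        # carry over the untouched block's vectors (sigma/tau recomputed by
        # extend; cheap relative to correctness, and keeps the bookkeeping
        # in one code path)
        for i, blk in enumerate(subspace.blocks[sym]):
            if blk == keep_block:
                new.extend([PairedVector(subspace.basis[sym][i], sym, blk)])
    return new


def schedule_frequencies(n_freqs: int, options: SolverOptions) -> np.ndarray:
    """Initial active frequency indices for dynamic scheduling (evenly spaced)."""
    k = min(options.dynamic_initial_count, n_freqs)
    return np.unique(np.round(np.linspace(0, n_freqs - 1, k)).astype(int))


def activate_neighbors(active: set, n_freqs: int) -> set:
    """Grid neighbors (adjacent indices) of the current active set."""
    new = set()
    for i in active:
        for j in (i - 1, i + 1):
            if 0 <= j < n_freqs and j not in active:
                new.add(j)
    return new


def run_cpp(
    problem: ResponseProblem,
    omegas_ev,
    options: SolverOptions | None = None,
    a_operators: list[OperatorGradient] | None = None,
    b_operators: list[OperatorGradient] | None = None,
    preconditioner: Preconditioner | None = None,
):
    """Drive the full iterative loop and return a :class:`ResponseSolution`.

    One shared trial subspace serves every equation, enumerated per
    (B operator, Cartesian component, frequency).  Initial guesses are the
    preconditioned property gradients; each iteration solves the reduced
    four-coupled system for all active equations, measures the four-component
    residual norms, expands the subspace with preconditioned residuals,
    optionally collapses oversized blocks and optionally activates
    neighboring frequencies (dynamic scheduling).
    """
    options = options or SolverOptions()
    omegas_ev = np.atleast_1d(np.asarray(omegas_ev, dtype=float))
    if b_operators is None:
        b_operators = problem.gradients_for(ELECTRIC_DIPOLE)
    if a_operators is None:
        a_operators = b_operators
    gamma_au = ev_to_au(options.gamma)
    omegas_au = ev_to_au(omegas_ev)

    subspace = TrialSubspace(problem, tda=options.tda,
                             lindep_threshold=options.lindep_threshold)
    pre = preconditioner or Preconditioner.from_problem(
        problem, tda=options.tda, regularization=options.regularization)

    equations: dict = {}
    for g in b_operators:
        subspace.register_gradient(g)
        for iw, w in enumerate(omegas_ev):
            eq = EquationState(g.operator_id, g.component, float(w), iw, g,
                               active=not options.dynamic_enabled)
            equations[eq.key] = eq
    for g in a_operators:
        subspace.register_gradient(g)

    n_freqs = omegas_ev.size
    if options.dynamic_enabled:
        active_freqs = set(schedule_frequencies(n_freqs, options).tolist())
        for eq in equations.values():
            eq.active = eq.omega_index in active_freqs
    else:
        active_freqs = set(range(n_freqs))

    def seed_equation(eq: EquationState) -> list[PairedVector]:
        res0 = (eq.gradient.real_part, np.zeros(problem.half_dim),
                eq.gradient.imag_part, np.zeros(problem.half_dim))
        return precondition(res0, pre, omegas_au[eq.omega_index], gamma_au,
                            problem, options.ci_reference)

    cands = []
    for eq in equations.values():
        if eq.active:
            cands.extend(seed_equation(eq))
    subspace.extend(cands)

    solutions: dict = {}
    aR = np.stack([g.real_part for g in a_operators])
    aI = np.stack([g.imag_part for g in a_operators])

    def contract_alpha(halves):
        X_gR, X_uR, X_uI, X_gI = halves
        return (2.0 * (aR @ X_gR + aI @ X_uI)
                + 2.0j * (aR @ X_gI - aI @ X_uR))

    n_iter = 0
    iteration_rows = []
    while n_iter < options.max_iterations:
        n_iter += 1
        # (b, c) reduced assembly + solve, grouped per frequency (the reduced
        # matrix depends only on omega; all components share the LU solve).
        by_freq: dict = {}
        for eq in equations.values():
            if eq.active:
                by_freq.setdefault(eq.omega_index, []).append(eq)
        for iw, eqs in sorted(by_freq.items()):
            M, (sl_gR, sl_uR, sl_uI, sl_gI) = assemble_reduced(
                subspace, omegas_au[iw], gamma_au)
            ng, nu = subspace.n(GERADE), subspace.n(UNGERADE)
            rhs = np.zeros((M.shape[0], len(eqs)))
            for k, eq in enumerate(eqs):
                p_g, p_u = subspace.gradient_rhs(eq.gradient)
                rhs[sl_gR, k] = p_g
                rhs[sl_uI, k] = p_u
            C = solve_reduced(M, rhs, options.regularization)
            for k, eq in enumerate(eqs):
                eq.coeffs = (C[sl_gR, k], C[sl_uR, k], C[sl_uI, k], C[sl_gI, k])

        # (d) residuals, convergence bookkeeping
        max_res = 0.0
        res_list = []
        new_cands = []
        for eq in equations.values():
            if not eq.active:
                continue
            X, res, total = back_project_and_residuals(
                subspace, eq.coeffs, eq.gradient, omegas_au[eq.omega_index], gamma_au)
            rel = total / max(eq.gradient.norm_full(), 1e-300)
            eq.residual_norm = rel
            eq.residual_history.append(rel)
            eq.alpha_history.append(contract_alpha(X))
            solutions[eq.key] = X
            if rel <= options.residual_threshold:
                eq.converged = True
            else:
                eq.converged = False
                res_list.append(rel)
                new_cands.extend(precondition(res, pre, omegas_au[eq.omega_index],
                                              gamma_au, problem, options.ci_reference))
            max_res = max(max_res, rel)

        subspace_sizes = subspace.pool_sizes()
        subspace_sizes_str = {f"{s[:1]}_{b[:3]}": n for (s, b), n in subspace_sizes.items()}
        all_active_converged = all(eq.converged for eq in equations.values() if eq.active)
        all_activated = len(active_freqs) == n_freqs

        # (f) collapse oversized blocks BEFORE admitting the fresh residual
        # directions, so the restart basis is the solution span and the new
        # trial vectors survive into the next reduced solve.
        if options.collapse_enabled and not (all_active_converged and all_activated):
            active_sols = [solutions[eq.key] for eq in equations.values()
                           if eq.active and eq.key in solutions]
            for blk, cap in ((ORBITAL, options.collapse_max_orb),
                             (CI, options.collapse_max_ci)):
                if subspace.n_block(blk) > cap:
                    logger.info("collapsing %s subspace (%d > %d)",
                                blk, subspace.n_block(blk), cap)
                    subspace = collapse_subspace(subspace, active_sols, blk,
                                                 options.collapse_svd_threshold)
                    regrads = {(g.operator_id, g.component): g
                               for g in list(b_operators) + list(a_operators)}
                    for g in regrads.values():
                        subspace.register_gradient(g)

        # (e) expansion
        n_added = 0
        if not (all_active_converged and all_activated):
            n_added = subspace.extend(new_cands)

        # (g) dynamic activation
        if options.dynamic_enabled and not all_activated:
            unconv = [eq.residual_norm for eq in equations.values()
                      if eq.active and not eq.converged]
            if not unconv or max(unconv) < options.dynamic_add_threshold:
                fresh = activate_neighbors(active_freqs, n_freqs)
                if fresh:
                    active_freqs |= fresh
                    for eq in equations.values():
                        if eq.omega_index in fresh:
                            eq.active = True
                    logger.info("activated %d neighboring frequencies", len(fresh))

        iter_converged = [eq for eq in equations.values() if eq.active and eq.converged]
        row = dict(iteration=n_iter,
                   n_active=sum(eq.active for eq in equations.values()),
                   n_converged=len(iter_converged),
                   max_residual=max_res,
                   mean_residual=float(np.mean(res_list)) if res_list else 0.0,
                   sigma_build_count=subspace.sigma_build_count,
                   **subspace_sizes_str)
        logger.info("iter %(iteration)d: active=%(n_active)d conv=%(n_converged)d "
                    "max_res=%(max_residual).2e sigma=%(sigma_build_count)d", row)
        iteration_rows.append(row)

        if all_active_converged and all_activated:
            break
        if n_added == 0 and not (options.dynamic_enabled and not all_activated):
            if not all_active_converged:
                logger.warning("no new trial vectors admitted; exiting with "
                               "%d unconverged equation(s)",
                               sum(not eq.converged for eq in equations.values()))
            break
    else:
        logger.warning("max_iterations=%d reached", options.max_iterations)

    solution = ResponseSolution(
        problem=problem, options=options, omegas_ev=omegas_ev,
        equations=equations, solutions=solutions,
        a_operators=a_operators, b_operators=b_operators,
        n_iterations=n_iter,
        sigma_build_count=subspace.sigma_build_count,
        converged=all(eq.converged for eq in equations.values()),
        iteration_table=iteration_rows,
    )
    solution._subspace = subspace  # kept for diagnostics/tests
    return solution
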