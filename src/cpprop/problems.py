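"""Response-problem data model and seeded synthetic problem generation.

A *response problem* bundles the paired electronic-Hessian blocks (A, B), the
paired metric blocks (Sigma, Delta), property-gradient vectors for one or more
perturbation operators, and two index maps used by the excitation-character
analysis:

* ``orbital_pair_map`` assigns every orbital-rotation parameter ``n`` to an
  ordered molecular-orbital pair ``(p, q)``;
* ``ci_transition_map`` is a (pair-count x n_ci) transition-density stand-in
  used to approximately attribute CI response to orbital excitations.

The full paired response matrices have the 2x2 excitation/de-excitation block
structure

    E2 = [[A, B], [B, A]],      S2 = [[Sigma, Delta], [-Delta, -Sigma]]

with A, B, Sigma symmetric and Delta antisymmetric, all real.  A problem is
*stable* when A+B and A-B are positive definite, which guarantees a real
excitation spectrum (the positive generalized eigenvalues of E2 x = w S2 x).

The synthetic generator emulates the structural properties a converged MCSCF
reference would provide -- stability, a prescribed spectral window, separate
orbital and CI parameter blocks, and dense dipole gradients -- without any
molecular integrals.  The Hessian/metric entries are structural stand-ins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg as sla

from .errors import GeneratorError
from .units import ev_to_au

__all__ = [
    "OperatorGradient",
    "ResponseProblem",
    "SolverOptions",
    "generate_synthetic_problem",
    "assemble_dense",
    "validate_problem",
    "ValidationReport",
    "ELECTRIC_DIPOLE", "ELECTRIC_DIPOLE_VELOCITY", "MAGNETIC_DIPOLE",
]

ELECTRIC_DIPOLE = "electric-dipole-length"
ELECTRIC_DIPOLE_VELOCITY = "electric-dipole-velocity"
MAGNETIC_DIPOLE = "magnetic-dipole"

COMPONENTS = ("x", "y", "z")


@dataclass(eq=False)
class OperatorGradient:
    """Property gradient of a perturbation operator over the excitation half space.

    The real part of the full-space gradient is embedded symmetrically
    (gerade), the imaginary part antisymmetrically (ungerade):

        B_full = (real + i*imag ; real - i*imag)

    so purely real operators (length-gauge electric dipole) populate only
    ``real_part`` and purely imaginary operators (magnetic dipole, velocity
    gauge) only ``imag_part``.
    """

    operator_id: str
    component: str
    real_part: np.ndarray
    imag_part: np.ndarray

    def __post_init__(self):
        self.real_part = np.asarray(self.real_part, dtype=float)
        self.imag_part = np.asarray(self.imag_part, dtype=float)
        if self.real_part.shape != self.imag_part.shape or self.real_part.ndim != 1:
            raise ValueError("real_part and imag_part must be 1-D of equal length")

    @property
    def half_dim(self) -> int:
        return self.real_part.size

    def full(self) -> np.ndarray:
        """Complex full-space (2N) gradient under the fixed pairing convention."""
        g = self.real_part + 1j * self.imag_part
        return np.concatenate([g, np.conj(g)])

    def norm_full(self) -> float:
        return math.sqrt(2.0 * (self.real_part @ self.real_part
                                + self.imag_part @ self.imag_part))


@dataclass
class ResponseProblem:
    """Paired response problem: Hessian/metric blocks, gradients and index maps."""

    n_orb: int
    n_ci: int
    A_block: np.ndarray
    B_block: np.ndarray
    Sigma_block: np.ndarray
    Delta_block: np.ndarray
    gradients: list[OperatorGradient] = field(default_factory=list)
    orbital_pair_map: np.ndarray = None  # (n_orb, 3) int: n, p, q
    ci_transition_map: np.ndarray = None  # (n_pairs, n_ci)
    metadata: dict = field(default_factory=dict)

    @property
    def half_dim(self) -> int:
        return self.n_orb + self.n_ci

    @property
    def full_dim(self) -> int:
        return 2 * self.half_dim

    def gradient(self, operator_id: str, component: str) -> OperatorGradient:
        for g in self.gradients:
            if g.operator_id == operator_id and g.component == component:
                return g
        raise KeyError(f"no gradient for ({operator_id}, {component})")

    def gradients_for(self, operator_id: str) -> list[OperatorGradient]:
        out = [g for g in self.gradients if g.operator_id == operator_id]
        if not out:
            raise KeyError(f"no gradients for operator {operator_id!r}")
        return sorted(out, key=lambda g: COMPONENTS.index(g.component))

    def orbital_slice(self) -> slice:
        return slice(0, self.n_orb)

    def ci_slice(self) -> slice:
        return slice(self.n_orb, self.half_dim)


@dataclass
class SolverOptions:
    """Settings for the iterative damped-response solver.

    Defaults follow common practice for this family of solvers: damping
    0.124 eV, residual-norm convergence threshold 1e-3 (relative to the
    gradient norm), Gram-Schmidt linear-dependence threshold 1e-8 and SVD
    screening threshold 1e-10 for subspace collapse.
    """

    gamma: float = 0.124                 # eV
    residual_threshold: float = 1e-3
    lindep_threshold: float = 1e-8
    collapse_max_orb: int = 400
    collapse_max_ci: int = 400
    collapse_enabled: bool = False
    collapse_svd_threshold: float = 1e-10
    dynamic_enabled: bool = False
    dynamic_initial_count: int = 4
    dynamic_add_threshold: float = 1e-2
    max_iterations: int = 200
    tda: bool = False
    seed: int = 0
    regularization: float = 1e-8
    ci_reference: Optional[np.ndarray] = None  # optional CI direction to project out

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.residual_threshold <= 0:
            raise ValueError("residual_threshold must be positive")
        if self.dynamic_initial_count < 1:
            raise ValueError("dynamic_initial_count must be >= 1")
        if self.collapse_enabled and (self.collapse_max_orb < 2 or self.collapse_max_ci < 2):
            raise ValueError("collapse maxima must be >= 2 when collapse is enabled")


def _sym(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


def _antisym(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m - m.T)


def _pair_table(n_orb: int) -> np.ndarray:
    """Distinct ordered (p, q) pairs on an occupied x virtual grid covering n_orb."""
    n_occ = max(1, math.ceil(math.sqrt(n_orb)))
    n_vir = math.ceil(n_orb / n_occ)
    table = np.empty((n_orb, 3), dtype=np.int64)
    n = 0
    for p in range(n_occ):
        for q in range(n_occ, n_occ + n_vir):
            if n >= n_orb:
                break
            table[n] = (n, p, q)
            n += 1
    return table


def positive_excitation_energies(problem: ResponseProblem, tda: bool = False) -> np.ndarray:
    """Positive generalized eigenvalues of the paired pencil, ascending (a.u.)."""
    E2, S2 = assemble_dense(problem, tda=tda)
    if tda:
        w = sla.eigh(E2, S2, eigvals_only=True)
        return np.sort(w)
    w = sla.eig(E2, S2, right=False)
    if np.max(np.abs(w.imag)) > 1e-8 * max(1.0, np.max(np.abs(w.real))):
        raise GeneratorError("complex generalized eigenvalues: problem not stable")
    w = np.sort(w.real)
    return w[w > 0]


def generate_synthetic_problem(
    n_orb: int,
    n_ci: int,
    seed: int,
    spectral_range: tuple[float, float] = (5.0, 15.0),
    coupling_scale: float = 1.0,
    stability_margin: float = 0.5,
    include_magnetic: bool = False,
    ci_map_rank: Optional[int] = None,
) -> ResponseProblem:
    """Generate a seeded, stable synthetic paired response problem.

    Parameters
    ----------
    n_orb, n_ci
        Sizes of the orbital-rotation and CI parameter blocks.
    seed
        RNG seed; equal seeds produce bit-identical problems.
    spectral_range
        (low, high) window in eV that must contain every excitation energy.
    coupling_scale
        Relative strength of the off-diagonal Hessian/metric couplings; 0
        yields a fully diagonal (decoupled) problem.
    stability_margin
        Eigenvalue floor (eV) enforced on A+B and A-B; must be positive.
    include_magnetic
        Also populate magnetic-dipole gradients (purely imaginary convention).
    ci_map_rank
        If given, truncate the CI transition map to this many nonzero columns,
        emulating a single-excitation-truncated map (leaves some CI response
        unattributable).
    """
    if n_orb < 1:
        raise ValueError("n_orb must be >= 1")
    if n_ci < 0:
        raise ValueError("n_ci must be >= 0")
    if stability_margin <= 0:
        raise ValueError("stability_margin must be positive")
    lo, hi = (ev_to_au(spectral_range[0]), ev_to_au(spectral_range[1]))
    if not 0 < lo < hi:
        raise ValueError("spectral_range must satisfy 0 < low < high")
    margin = ev_to_au(stability_margin)

    rng = np.random.default_rng(seed)
    N = n_orb + n_ci
    span = hi - lo
    # Diagonal energies inside the window, away from the edges.
    d = rng.uniform(lo + 0.08 * span, hi - 0.08 * span, size=N)
    # Random symmetric/antisymmetric couplings; perturbative scale so the
    # spectrum stays inside the window after a few repair passes.
    eta = 0.5 * coupling_scale
    W_A = _sym(rng.standard_normal((N, N)))
    W_B = _sym(rng.standard_normal((N, N)))
    W_S = _sym(rng.standard_normal((N, N)))
    W_D = _antisym(rng.standard_normal((N, N)))

    gradients = []
    for comp in COMPONENTS:
        gradients.append(OperatorGradient(ELECTRIC_DIPOLE, comp,
                                          rng.standard_normal(N), np.zeros(N)))
    if include_magnetic:
        for comp in COMPONENTS:
            gradients.append(OperatorGradient(MAGNETIC_DIPOLE, comp,
                                              np.zeros(N), rng.standard_normal(N)))

    # CI transition map: column-orthonormal by construction (complete when
    # n_ci <= n_orb), optionally rank-truncated.
    n_pairs = n_orb
    T = np.zeros((n_pairs, n_ci))
    if n_ci > 0:
        q_cols = min(n_ci, n_pairs)
        Q, _ = np.linalg.qr(rng.standard_normal((n_pairs, q_cols)))
        T[:, :q_cols] = Q
        if n_ci > n_pairs:
            extra = rng.standard_normal((n_pairs, n_ci - n_pairs))
            T[:, n_pairs:] = extra / np.linalg.norm(extra, axis=0)
        if ci_map_rank is not None:
            T[:, ci_map_rank:] = 0.0

    scale_coupling = 1.0
    for attempt in range(8):
        s = eta * scale_coupling
        A = np.diag(d) + (0.05 * span / math.sqrt(N)) * s * W_A
        B = (0.025 * span / math.sqrt(N)) * s * W_B
        Sigma = np.eye(N) + (0.25 / math.sqrt(N)) * s * W_S
        Delta = (0.1 / math.sqrt(N)) * s * W_D

        # Repair 1: Sigma positive definite with a comfortable floor.
        w_S = np.linalg.eigvalsh(Sigma)
        if w_S.min() < 0.5:
            Sigma = Sigma + (0.5 - w_S.min()) * np.eye(N)
        # Repair 2: stability floor on A+B and A-B via a diagonal shift of A.
        m = min(np.linalg.eigvalsh(A + B).min(), np.linalg.eigvalsh(A - B).min())
        if m < margin:
            A = A + (margin - m) * np.eye(N)

        problem = ResponseProblem(
            n_orb=n_orb, n_ci=n_ci,
            A_block=A, B_block=B, Sigma_block=Sigma, Delta_block=Delta,
            gradients=gradients,
            orbital_pair_map=_pair_table(n_orb),
            ci_transition_map=T,
            metadata={
                "seed": int(seed),
                "spectral_range_eV": [float(spectral_range[0]), float(spectral_range[1])],
                "coupling_scale": float(coupling_scale),
                "stability_margin_eV": float(stability_margin),
                "stable": True,
                "generator": "cpprop synthetic paired response problem "
                             "(structural stand-in, no molecular integrals)",
            },
        )
        try:
            w = positive_excitation_energies(problem)
        except GeneratorError:
            scale_coupling *= 0.5
            continue
        if w.size == 0 or w.min() <= 0:
            scale_coupling *= 0.5
            continue
        if w.min() >= lo and w.max() <= hi:
            return problem
        # Repair 3: rescale the Hessian so the spectrum fits the window;
        # the pencil eigenvalues scale linearly with A, B.
        c = min((hi - 0.01 * span) / w.max(), 1.0)
        c = max(c, (lo + 0.01 * span) / w.min())
        d = d * c
        scale_coupling *= 0.7

    raise GeneratorError(
        "could not generate a stable problem inside the spectral window; "
        "reduce coupling_scale or widen spectral_range"
    )


def assemble_dense(problem: ResponseProblem, tda: bool = False):
    """Assemble the full-space dense matrices (E2, S2).

    RPA: 2N-dimensional paired structure E2 = [[A,B],[B,A]],
    S2 = [[Sigma,Delta],[-Delta,-Sigma]].  TDA: the B and Delta blocks are
    neglected and only the N-dimensional excitation block (A, Sigma) remains.
    """
    A, B = problem.A_block, problem.B_block
    S, D = problem.Sigma_block, problem.Delta_block
    if tda:
        return A.copy(), S.copy()
    E2 = np.block([[A, B], [B, A]])
    S2 = np.block([[S, D], [-D, -S]])
    return E2, S2


@dataclass
class ValidationReport:
    """Per-invariant pass/fail report with the worst deviation of each check."""

    checks: dict

    @property
    def all_passed(self) -> bool:
        return all(c["passed"] for c in self.checks.values())

    def __str__(self):
        lines = []
        for name, c in self.checks.items():
            status = "PASS" if c["passed"] else "FAIL"
            lines.append(f"{name:<22s} {status}  max_dev={c['deviation']:.3e}  {c.get('detail','')}")
        return "\n".join(lines)


def validate_problem(problem: ResponseProblem) -> ValidationReport:
    """Check the structural invariants of a response problem; never raises."""
    checks = {}

    def rel_dev(m, ref):
        denom = max(np.abs(ref).max(), 1e-300)
        return np.abs(m).max() / denom

    for name, M in (("A_symmetric", problem.A_block),
                    ("B_symmetric", problem.B_block),
                    ("Sigma_symmetric", problem.Sigma_block)):
        dev = rel_dev(M - M.T, M) if np.abs(M).max() > 0 else 0.0
        checks[name] = {"passed": dev <= 1e-12, "deviation": dev}

    D = problem.Delta_block
    asym = D + D.T
    dev = np.abs(asym).max() / max(np.abs(D).max(), 1.0)
    detail = ""
    if dev > 1e-12:
        i, j = np.unravel_index(np.argmax(np.abs(asym)), asym.shape)
        detail = f"entry ({i},{j})"
    checks["Delta_antisymmetric"] = {"passed": dev <= 1e-12, "deviation": dev,
                                     "detail": detail}

    try:
        mins = min(np.linalg.eigvalsh(problem.A_block + problem.B_block).min(),
                   np.linalg.eigvalsh(problem.A_block - problem.B_block).min())
        checks["stability"] = {"passed": bool(mins > 0), "deviation": float(-min(mins, 0.0)),
                               "detail": f"min eig(A+/-B) = {mins:.3e}"}
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        checks["stability"] = {"passed": False, "deviation": np.inf, "detail": str(exc)}

    w_S = np.linalg.eigvalsh(problem.Sigma_block)
    checks["Sigma_posdef"] = {"passed": bool(w_S.min() > 0), "deviation": float(-min(w_S.min(), 0.0))}

    pm = problem.orbital_pair_map
    ok = pm is not None and pm.shape == (problem.n_orb, 3) and \
        np.array_equal(np.sort(pm[:, 0]), np.arange(problem.n_orb))
    checks["pair_map_coverage"] = {"passed": bool(ok), "deviation": 0.0 if ok else 1.0}

    bad = [g for g in problem.gradients if g.half_dim != problem.half_dim]
    checks["gradient_lengths"] = {"passed": not bad, "deviation": float(len(bad))}

    return ValidationReport(checks)
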