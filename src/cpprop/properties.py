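"""Spectra and analysis: polarizability tensors, absorption/dispersion
cross-sections, mixed electric-magnetic (ECD/ORD) response, orbital-excitation
decomposition, and post-broadening.

Cross-section convention: with the isotropic average abar = tr(alpha)/3, the
linear absorption cross-section is sigma_abs(w) = (4 pi w / c) Im abar(w) in
atomic units (c = 137.035999); the dispersion cross-section uses Re abar with
the same prefactor.  The mixed tensor G' is reported as the raw contraction of
the electric gradients with the magnetic-dipole response (arbitrary units; no
experimental-unit constants are applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import MissingComponentError, UnmappedIndexError
from .problems import (ELECTRIC_DIPOLE, MAGNETIC_DIPOLE, OperatorGradient,
                       ResponseProblem)
from .solver import ResponseSolution
from .units import SPEED_OF_LIGHT_AU, ev_to_au

__all__ = [
    "Spectrum", "DecompositionReport",
    "polarizability_tensor", "absorption_dispersion", "ecd_ord",
    "decompose_contributions", "broaden_post", "spectrum_from_solution",
]

CROSS_SECTION_PREFACTOR = 4.0 * np.pi / SPEED_OF_LIGHT_AU


@dataclass
class Spectrum:
    """Complex polarizability tensors on a frequency grid plus cross-sections.

    ``alpha[w, i, j]`` is indexed (frequency, A component, B component) with
    components ordered x, y, z.  ``sigma_abs``/``sigma_disp`` are the
    absorption/dispersion cross-sections; ``G_prime`` is present when a
    magnetic response was computed.  All frequencies in eV, tensors in a.u.
    """

    omegas: np.ndarray
    alpha: np.ndarray
    sigma_abs: np.ndarray = None
    sigma_disp: np.ndarray = None
    G_prime: np.ndarray = None
    gauge: str = "length"
    metadata: dict = field(default_factory=dict)


@dataclass
class DecompositionReport:
    """Per-orbital-pair partial absorption spectra that sum to the total.

    ``contributions[(p, q)]`` is the orbital-block partial spectrum over the
    grid (Cartesian-summed); ``ci_mapped[(p, q)]`` the CI-block contribution
    attributed through the transition-density map; ``unmapped_ci`` whatever
    CI response the (possibly truncated) map could not attribute.
    """

    omegas: np.ndarray
    contributions: dict
    ci_mapped: dict
    unmapped_ci: np.ndarray
    total: np.ndarray

    def conservation_error(self) -> float:
        s = np.zeros_like(self.total)
        for v in self.contributions.values():
            s = s + v
        for v in self.ci_mapped.values():
            s = s + v
        s = s + self.unmapped_ci
        return float(np.max(np.abs(s - self.total)))


def _halves_for(solution: ResponseSolution, operator_id: str):
    """Solution halves for components x, y, z of one B operator, per frequency."""
    nw = solution.omegas_ev.size
    out = []
    missing = []
    for comp in "xyz":
        per_w = []
        for iw in range(nw):
            key = (operator_id, comp, iw)
            if key not in solution.solutions:
                missing.append(key)
            else:
                per_w.append(solution.solutions[key])
        out.append(per_w)
    if missing:
        solved = sorted({(k[0], k[1]) for k in solution.solutions})
        raise MissingComponentError(
            f"missing solved components {missing[:3]}...; solved pairs: {solved}")
    return out


def polarizability_tensor(
    solution: ResponseSolution,
    a_operators: list[OperatorGradient] | None = None,
    operator_id: str = ELECTRIC_DIPOLE,
) -> np.ndarray:
    """Contract A gradients with the response solutions of ``operator_id``.

    alpha_ab(w) = A_a^dagger X_b(w) in the real-algebra form
    2 (aR.X_gR + aI.X_uI) + 2i (aR.X_gI - aI.X_uR).
    """
    a_operators = a_operators or solution.a_operators
    halves = _halves_for(solution, operator_id)
    nw = solution.omegas_ev.size
    alpha = np.empty((nw, len(a_operators), 3), dtype=complex)
    for i, ga in enumerate(a_operators):
        aR, aI = ga.real_part, ga.imag_part
        for j in range(3):
            for iw in range(nw):
                X_gR, X_uR, X_uI, X_gI = halves[j][iw]
                alpha[iw, i, j] = (2.0 * (aR @ X_gR + aI @ X_uI)
                                   + 2.0j * (aR @ X_gI - aI @ X_uR))
    return alpha


def absorption_dispersion(alpha: np.ndarray, omegas) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic absorption and dispersion cross-sections from alpha[w, i, j]."""
    omegas_au = ev_to_au(np.atleast_1d(np.asarray(omegas, dtype=float)))
    iso = np.trace(alpha, axis1=1, axis2=2) / 3.0
    pref = CROSS_SECTION_PREFACTOR * omegas_au
    return pref * iso.imag, pref * iso.real


def ecd_ord(
    solution: ResponseSolution,
    electric_operators: list[OperatorGradient] | None = None,
    magnetic_operator_id: str = MAGNETIC_DIPOLE,
) -> np.ndarray:
    """Mixed electric-magnetic polarizability tensor G'(w).

    Contraction of the electric A gradients with the magnetic-dipole response
    solutions; the trace traces out the ECD/ORD curves (arbitrary units).
    """
    electric_operators = electric_operators or solution.a_operators
    try:
        return polarizability_tensor(solution, electric_operators,
                                     operator_id=magnetic_operator_id)
    except MissingComponentError as exc:
        raise MissingComponentError(
            f"no solved magnetic-dipole response: {exc}") from exc


def spectrum_from_solution(
    solution: ResponseSolution,
    electric_id: str = ELECTRIC_DIPOLE,
    magnetic_id: str = MAGNETIC_DIPOLE,
) -> Spectrum:
    """Assemble a :class:`Spectrum` (alpha, cross-sections, optional G')."""
    alpha = polarizability_tensor(solution, operator_id=electric_id)
    sigma_abs, sigma_disp = absorption_dispersion(alpha, solution.omegas_ev)
    gp = None
    if any(k[0] == magnetic_id for k in solution.solutions):
        gp = ecd_ord(solution, magnetic_operator_id=magnetic_id)
    gauge = "velocity" if electric_id == "electric-dipole-velocity" else "length"
    return Spectrum(omegas=solution.omegas_ev.copy(), alpha=alpha,
                    sigma_abs=sigma_abs, sigma_disp=sigma_disp,
                    G_prime=gp, gauge=gauge,
                    metadata={"converged": solution.converged,
                              "n_iterations": solution.n_iterations,
                              "sigma_build_count": solution.sigma_build_count})


def decompose_contributions(
    problem: ResponseProblem,
    solution: ResponseSolution,
    a_operators: list[OperatorGradient] | None = None,
    operator_id: str = ELECTRIC_DIPOLE,
) -> DecompositionReport:
    """Decompose the absorption cross-section into orbital-pair contributions.

    The elementwise products of the A-gradient entries with the solution
    entries are grouped by (p, q) through the orbital pair map; the three
    Cartesian (diagonal) components are summed into one partial spectrum per
    pair.  CI-block products are attributed through the squared
    transition-density weights; with a complete (column-orthonormal) map the
    unmapped residual vanishes and the decomposition is exactly conservative.
    """
    a_operators = a_operators or solution.a_operators
    halves = _halves_for(solution, operator_id)
    nw = solution.omegas_ev.size
    N = problem.half_dim
    omegas_au = ev_to_au(solution.omegas_ev)
    pref = CROSS_SECTION_PREFACTOR * omegas_au / 3.0

    pm = problem.orbital_pair_map
    if pm is None or pm.shape[0] < problem.n_orb:
        raise UnmappedIndexError("orbital_pair_map must cover the orbital block")
    pair_of = {int(n): (int(p), int(q)) for n, p, q in pm}
    for n in range(problem.n_orb):
        if n not in pair_of:
            raise UnmappedIndexError(f"orbital parameter {n} has no (p, q) mapping")

    # Elementwise Im(alpha_aa) contribution per half-space element, summed
    # over the three diagonal Cartesian pairings, cross-section weighted.
    elem = np.zeros((nw, N))
    for j, comp in enumerate("xyz"):
        ga = a_operators[j]
        aR, aI = ga.real_part, ga.imag_part
        for iw in range(nw):
            X_gR, X_uR, X_uI, X_gI = halves[j][iw]
            elem[iw] += pref[iw] * 2.0 * (aR * X_gI - aI * X_uR)

    total = elem.sum(axis=1)

    contributions: dict = {}
    for n in range(problem.n_orb):
        key = pair_of[n]
        contributions[key] = contributions.get(key, 0.0) + elem[:, n]

    ci_mapped: dict = {}
    unmapped = np.zeros(nw)
    if problem.n_ci:
        T = problem.ci_transition_map
        W = T ** 2  # attribution weights per (pair, ci)
        colsum = W.sum(axis=0)
        ci_elem = elem[:, problem.ci_slice()]  # (nw, n_ci)
        mapped = ci_elem @ W.T                 # (nw, n_pairs)
        for row in pm:
            key = (int(row[1]), int(row[2]))
            ci_mapped[key] = ci_mapped.get(key, 0.0) + mapped[:, int(row[0])]
        unmapped = ci_elem @ (1.0 - colsum)

    return DecompositionReport(omegas=solution.omegas_ev.copy(),
                               contributions=contributions,
                               ci_mapped=ci_mapped,
                               unmapped_ci=unmapped,
                               total=total)


def broaden_post(spectrum: Spectrum, hwhm: float, kernel: str = "gaussian") -> Spectrum:
    """Convolve the cross-section curves with a Gaussian of the given HWHM (eV).

    Applied to Lorentzian-damped curves this yields a Voigt-like profile.
    The discrete kernel is normalized, so the integrated intensity away from
    the grid edges is preserved.  Requires a uniform frequency grid.
    """
    if kernel != "gaussian":
        raise ValueError(f"unsupported kernel {kernel!r}")
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    w = spectrum.omegas
    dw = np.diff(w)
    if w.size < 2 or not np.allclose(dw, dw[0], rtol=1e-8):
        raise ValueError("broadening requires a uniform frequency grid")
    sigma_pts = hwhm / np.sqrt(2.0 * np.log(2.0)) / dw[0]

    def conv(y):
        if y is None:
            return None
        if np.iscomplexobj(y):
            return (gaussian_filter1d(y.real, sigma_pts, axis=0, mode="nearest")
                    + 1j * gaussian_filter1d(y.imag, sigma_pts, axis=0, mode="nearest"))
        return gaussian_filter1d(y, sigma_pts, axis=0, mode="nearest")

    return Spectrum(omegas=w.copy(), alpha=conv(spectrum.alpha),
                    sigma_abs=conv(spectrum.sigma_abs),
                    sigma_disp=conv(spectrum.sigma_disp),
                    G_prime=conv(spectrum.G_prime), gauge=spectrum.gauge,
                    metadata={**spectrum.metadata, "broadening_hwhm_eV": hwhm})
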