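"""Compute a damped absorption spectrum and verify it against the dense oracle.

Generates a stable synthetic paired response problem, solves the damped
response equations on a 60-point grid with the iterative subspace solver,
and compares the resulting absorption cross-section with the
Lorentzian-broadened stick spectrum from the dense eigensolver.
"""

import numpy as np

from cpprop import (SolverOptions, generalized_eigensolve,
                    generate_synthetic_problem, run_cpp,
                    spectrum_from_solution, sum_over_states_alpha)
from cpprop.properties import absorption_dispersion

problem = generate_synthetic_problem(n_orb=60, n_ci=20, seed=7,
                                     spectral_range=(5.0, 15.0))
omegas = np.linspace(4.0, 16.0, 60)

solution = run_cpp(problem, omegas, SolverOptions(gamma=0.124,
                                                  residual_threshold=1e-4))
spectrum = spectrum_from_solution(solution)

eigen = generalized_eigensolve(problem)
keys = [("electric-dipole-length", c) for c in "xyz"]
alpha_sos = sum_over_states_alpha(eigen, keys, keys, omegas, 0.124)
sigma_sos, _ = absorption_dispersion(alpha_sos, omegas)

dev = np.max(np.abs(spectrum.sigma_abs - sigma_sos)) / sigma_sos.max()
peak = omegas[np.argmax(spectrum.sigma_abs)]

print(f"converged in {solution.n_iterations} iteration(s), "
      f"{solution.sigma_build_count} Hessian applications")
print(f"strongest absorption at {peak:.2f} eV "
      f"(lowest excitation: {eigen.energies[0]:.2f} eV)")
print(f"max relative deviation from the sum-over-states oracle: {dev:.2e}")
print("-> the iterative damped spectrum reproduces the Lorentzian-broadened")
print("   stick spectrum of the full eigensolve, without solving any states.")
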