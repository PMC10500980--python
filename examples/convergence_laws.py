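"""The two numerical laws of the damped-response iteration.

A single response equation is iterated to a tight residual threshold while
recording the polarizability at every step.  The per-iteration property
change falls off as the *square* of the residual norm, so a residual
threshold of 10^-n delivers about 2n correct decimal digits.
"""

import numpy as np

from cpprop import SolverOptions, direct_inversion_alpha, \
    generate_synthetic_problem, run_cpp

DIP = "electric-dipole-length"

problem = generate_synthetic_problem(n_orb=80, n_ci=20, seed=3,
                                     spectral_range=(2.0, 30.0))
aops = problem.gradients_for(DIP)[:1]
solution = run_cpp(problem, [5.5],
                   SolverOptions(residual_threshold=1e-9, max_iterations=100),
                   a_operators=aops, b_operators=aops)
eq = solution.equations[(DIP, "x", 0)]
res = np.array(eq.residual_history)
alpha = np.array([a[0] for a in eq.alpha_history])
dalpha = np.abs(np.diff(alpha))
mask = (res[:-1] < 0.5) & (res[:-1] > 1e-7) & (dalpha > 0)
slope = np.polyfit(np.log10(res[:-1][mask]), np.log10(dalpha[mask]), 1)[0]
print(f"single equation converged in {solution.n_iterations} iterations")
print(f"log-log slope of |delta alpha| vs residual norm: {slope:.2f} "
      "(quadratic: 2)")

ref = direct_inversion_alpha(problem, [3.0], 0.124,
                             problem.gradients_for(DIP),
                             problem.gradients_for(DIP))[0]
iso_ref = np.trace(ref) / 3
for n in (2, 3, 4):
    s = run_cpp(problem, [3.0], SolverOptions(residual_threshold=10.0 ** -n))
    iso = np.mean([s.equations[(DIP, c, 0)].alpha_history[-1][i]
                   for i, c in enumerate("xyz")])
    digits = -np.log10(abs(iso - iso_ref) / abs(iso_ref))
    print(f"threshold 1e-{n}: {digits:4.1f} correct digits (law predicts ~{2*n})")
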