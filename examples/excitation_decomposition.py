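"""Attribute an absorption spectrum to individual orbital excitations.

The orbital block of the response is decomposed exactly through the known
parameter-to-orbital-pair map; the CI block is attributed approximately via
squared transition-density weights.  The partial spectra sum to the total
cross-section at every frequency.
"""

import numpy as np

from cpprop import (SolverOptions, decompose_contributions,
                    generate_synthetic_problem, run_cpp, spectrum_from_solution)

problem = generate_synthetic_problem(n_orb=40, n_ci=15, seed=11)
omegas = np.linspace(5.0, 15.0, 40)

solution = run_cpp(problem, omegas, SolverOptions(residual_threshold=1e-5))
spectrum = spectrum_from_solution(solution)
report = decompose_contributions(problem, solution)

totals = {pair: np.trapezoid(np.abs(curve + report.ci_mapped.get(pair, 0.0)),
                             omegas)
          for pair, curve in report.contributions.items()}
top = sorted(totals.items(), key=lambda kv: -kv[1])[:5]

print("top orbital excitations by integrated |partial cross-section|:")
for (p, q), area in top:
    share = area / sum(totals.values())
    print(f"  orbital {p:3d} -> {q:3d}: {area:9.3f} a.u.  ({share:5.1%})")
print(f"conservation error: {report.conservation_error():.2e} "
      f"(partial spectra sum to sigma_abs exactly)")
print(f"unmapped CI residual: {np.abs(report.unmapped_ci).max():.2e} "
      "(zero: the transition map is complete)")
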