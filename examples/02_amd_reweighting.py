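"""Recover a free-energy surface from a boosted (accelerated-MD-like) sample.

Draws 50,000 (theta1, theta2) points from a two-well density sampled under a
known boost potential dV, reweights them with the 10th-order Maclaurin
series of exp(beta*dV), and compares the resulting PMF with the analytic
reference.  The planted wells sit at (70, 70) and (100, 100) degrees with a
1 kcal/mol depth difference.
"""

import numpy as np

from mabshape import BoostedSpec, generate_boosted_samples, reweight_fes, select_min_energy_frames
from mabshape.amd import default_theta_edges

spec = BoostedSpec(seed=7, n_samples=50_000)
sample = generate_boosted_samples(spec)
edges = default_theta_edges(2.5)
grid = reweight_fes(sample.angles, sample.boost, edges, edges, k_max=10)

analytic = spec.analytic_pmf(edges, edges)
mask = grid.counts >= 100
err = np.max(np.abs(grid.pmf[mask] - analytic[mask]))

t1, t2 = grid.minimum()
i_y = grid.bin_of(np.array([70.0]), np.array([70.0]))
i_t = grid.bin_of(np.array([100.0]), np.array([100.0]))
gap = float(grid.pmf[i_t][0] - grid.pmf[i_y][0])
min_frames = select_min_energy_frames(grid, sample.angles, cutoff=0.5)

print(f"rejection efficiency:      {sample.efficiency:.2f}")
print(f"PMF minimum at theta = ({t1:.1f}, {t2:.1f}) deg   planted (70, 70)")
print(f"well depth gap:            {gap:.2f} kcal/mol      planted 1.00")
print(f"max |PMF - analytic|:      {err:.3f} kcal/mol on {mask.sum()} populated bins")
print(f"minimum-energy frames (PMF < 0.5): {len(min_frames)} of {len(sample.angles)}")
# The truncated-series weights reproduce the analytic surface to ~0.1
# kcal/mol wherever the sample is dense; the PMF < 0.5 kcal/mol frame set is
# what the downstream descriptor analyses consume.
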