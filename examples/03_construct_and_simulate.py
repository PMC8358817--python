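"""Construct a stochastic Murray-law tree, solve its hemodynamics, analyse it.

Grows an arterial tree from a 300 um root down to the 10 um capillary
cutoff with per-bifurcation exponents k ~ N(2.7, 0.1) and asymmetry ratios
lambda ~ N(0.8, 0.05), solves Poiseuille network flows (in-vivo rheology,
1 mmHg inlet, 0 mmHg terminal outlets) and reports the flow heterogeneity
metrics.
"""

import warnings

import numpy as np

from hemofractal import (
    ConstructionConfig,
    ScaleRangeWarning,
    construct_tree,
    solve_network,
)
from hemofractal.experiments import analyze_tree

warnings.simplefilter("ignore", ScaleRangeWarning)

cfg = ConstructionConfig(k_mean=2.7, k_sd=0.1, lambda_mean=0.8, lambda_sd=0.05)
tree = construct_tree(cfg, np.random.default_rng(42))
solution = solve_network(tree)
report = analyze_tree(tree)

print(f"vessels: {report['n_segments']}, max generation: {report['max_generation']}")
print(f"max junction conservation residual: {solution.max_conservation_residual:.2e}")
print(f"D_Q = {report['d_q']:.3f} (fit R^2 = {report['r_squared']:.4f})")
print(f"delta_alpha = {report['delta_alpha']:.3f}, f_max = {report['f_max']:.3f}")
print(f"CV = {report['cv']:.2f}")
print(
    "\nD_Q below 1 and a nonzero delta_alpha quantify how unevenly the "
    "simulated perfusion\nis distributed over this asymmetric tree; flows "
    "conserve at every junction to ~1e-15."
)
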