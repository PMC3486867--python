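"""Recovering microscopic pKa values from synthetic constant-pH output.

Simulates an 8-point pH titration of the reference cycle, then fits the
protonated fractions three ways: pooled over all frames (which yields a
midpoint near the APPARENT pKa - the quantity an unresolved experiment
measures) and conditioned on each conformation (which recovers the two
microscopic pKa values the pooled fit cannot see).
"""

import numpy as np

from phlinkage import KineticParams, ThermoCycle, apparent_pka, fit_titration, titration_experiment

cycle = ThermoCycle(8.5, 4.3, 100.0)
grid = np.arange(3.0, 10.5, 1.0)
exp = titration_experiment(
    cycle, grid, KineticParams(n_steps=200_000, seed=101), keep_trajectories=False
)

pooled = fit_titration(exp.overall)
closed = fit_titration(exp.closed)
open_ = fit_titration(exp.open)

print(f"pH grid {grid[0]:.0f}..{grid[-1]:.0f}, 2e5 frames per point")
print(f"pooled fit        : {pooled}")
print(f"closed-conditioned: {closed}   (true 8.5)")
print(f"open-conditioned  : {open_}   (true 4.3)")

rebuilt = ThermoCycle(closed.pka, open_.pka, cycle.kd)
print(f"apparent pKa from rebuilt cycle: {apparent_pka(rebuilt):.2f} (analytic {apparent_pka(cycle):.2f})")
print("-> the pooled titration midpoint sits between the microscopic values;")
print("   only conformation-resolved counts recover 8.5 and 4.3.")
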