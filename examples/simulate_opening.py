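"""A closed, protonated protein dropped into pH 7.5 solvent.

Runs the coupled protonation/conformation kinetic Monte Carlo chain from
the closed-protonated state at pH 7.5, where the stable state is open and
deprotonated.  Detects the opening transition from the Asp30-Leu130
distance (hydrogen bond ~3.5 Å closed, ~8 Å open) and shows the windowed
microscopic pKa falling as the residue's environment changes.
"""

import numpy as np

from phlinkage import (
    KineticParams,
    SimState,
    ThermoCycle,
    detect_transition,
    running_pka,
    simulate,
    summarize_observable,
)

cycle = ThermoCycle(8.5, 4.3, 100.0)
kin = KineticParams(n_steps=100_000, seed=21, dt_ns=1e-4)
traj = simulate(cycle, ph=7.5, kin=kin, start=SimState("closed", True))

open_frames = traj.frames["conformation"] == "open"
print(f"{len(traj)} frames at pH 7.5; open fraction {open_frames.mean():.2f}")

idx = detect_transition(
    traj.frames["d_asp30_leu130"].to_numpy(),
    ref_a=(3.5, 0.3), ref_b=(8.0, 1.0), persistence=50, window=100,
)
print(f"Asp30-Leu130 contact breaks at frame {idx} (t = {idx * kin.dt_ns:.2f} ns)")

for label, sel in (("closed", ~open_frames), ("open", open_frames)):
    mean, sd = summarize_observable(traj.frames.loc[sel, "sasa"])
    print(f"Asp30 SASA while {label}: {mean:.0f} +- {sd:.0f} A^2")

trace = running_pka(traj, window=1000)
early = trace["pka"].iloc[1000:3000].dropna()
late = trace["pka"].iloc[-20_000:].dropna()
print(f"windowed pKa, just after start : {early.mean():.1f}")
print(f"windowed pKa, late open regime : {late.mean():.1f} (many windows censored '<')")
print("-> deprotonation precedes opening; once open, the residue titrates")
print("   like a solvent-exposed carboxylate instead of a buried one.")
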