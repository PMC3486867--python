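"""Per-frame trajectory container shared by the simulator and the estimators.

Emulates the shape of constant-pH MD output: one row per frame with the
conformation label, the binary protonation state of the titratable residue,
two gating distances (the Asp30–Leu130 hydrogen bond that pins the loops
shut, and the Asp35–Asp129 distance that opens the ligand escape route) and
the residue's solvent-accessible surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "FRAME_COLUMNS", "OBSERVABLE_COLUMNS"]

OBSERVABLE_COLUMNS = ("d_asp30_leu130", "d_asp35_asp129", "sasa")
FRAME_COLUMNS = ("time_ns", "conformation", "protonated") + OBSERVABLE_COLUMNS


@dataclass
class Trajectory:
    """Frame table plus the run metadata needed to interpret it.

    ``frames`` columns: time_ns (strictly increasing), conformation
    ('closed'/'open'), protonated (0/1), d_asp30_leu130 and d_asp35_asp129
    in Å, sasa in Å².  ``dt_ns`` is the fictitious time per frame.
    """

    frames: pd.DataFrame
    ph: float
    seed: int | None = None
    dt_ns: float = 1e-4

    def __post_init__(self) -> None:
        missing = [c for c in FRAME_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"trajectory frames missing columns: {missing}")
        t = self.frames["time_ns"].to_numpy(float)
        if t.size == 0:
            raise ValueError("trajectory must contain at least one frame")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time_ns must be strictly increasing")
        obs = self.frames[list(OBSERVABLE_COLUMNS)].to_numpy(float)
        if np.any(obs < 0):
            raise ValueError("distances and SASA must be non-negative")
        bad = set(self.frames["conformation"].unique()) - {"closed", "open"}
        if bad:
            raise ValueError(f"unknown conformation labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def protonated_fraction(self) -> float:
        return float(self.frames["protonated"].mean())

    def metadata(self) -> dict:
        return {"ph": self.ph, "seed": self.seed, "dt_ns": self.dt_ns, "n_frames": len(self)}
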