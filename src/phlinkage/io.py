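"""File I/O and run configuration.

Trajectories and titration tables travel as headered CSV ('.' decimal, no
locale dependence), scalar results as JSON with full double precision;
printed-precision rounding is applied only in report text.  Every simulation
writes a JSON manifest echoing all parameters and the seed so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import KineticParams
from .estimation import TitrationSeries
from .linkage import ThermoCycle, SignalModel
from .trajectory import FRAME_COLUMNS, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "read_trajectory",
    "write_trajectory",
    "read_titration",
    "write_titration",
    "write_json",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Flat run configuration; defaults are the reference-model values."""

    pk_closed: float = 8.5
    pk_open: float = 4.3
    kd: float = 100.0
    alpha: float = 0.03
    beta: float = 0.55
    n_steps: int = 100_000
    mc_interval: int = 10
    p_conf_attempt: float = 0.01
    seed: int = 0
    burn_in: float = 0.1
    dt_ns: float = 1e-4
    window: int = 100
    block_length: int = 100

    def __post_init__(self) -> None:
        # constructing the domain objects runs their validators
        self.cycle()
        self.signal_model()
        self.kinetics()
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")

    def cycle(self) -> ThermoCycle:
        return ThermoCycle(self.pk_closed, self.pk_open, self.kd)

    def signal_model(self) -> SignalModel:
        return SignalModel(self.alpha, self.beta)

    def kinetics(self, **overrides) -> KineticParams:
        base = dict(
            n_steps=self.n_steps,
            mc_interval=self.mc_interval,
            p_conf_attempt=self.p_conf_attempt,
            seed=self.seed,
            burn_in=self.burn_in,
            dt_ns=self.dt_ns,
        )
        base.update({k: v for k, v in overrides.items() if v is not None})
        return KineticParams(**base)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a flat YAML key-value config; explicit overrides win.

    Unknown keys raise, listing them; value constraints are enforced by the
    domain-type validators.  ``overrides`` equal to None are ignored so CLI
    flags only take precedence when actually given.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat key-value mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown} (known: {sorted(known)})")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the frame table as headered CSV plus a sidecar JSON manifest."""
    path = Path(path)
    traj.frames.to_csv(path, index=False, columns=list(FRAME_COLUMNS))
    write_manifest(traj.metadata(), path.with_suffix(path.suffix + ".manifest.json"))


def read_trajectory(
    path: str | Path, ph: float | None = None, dt_ns: float | None = None
) -> Trajectory:
    """Read a trajectory CSV; metadata comes from the sidecar manifest unless given."""
    path = Path(path)
    frames = pd.read_csv(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".manifest.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if ph is None:
        ph = meta.get("ph")
    if ph is None:
        raise ValueError(f"pH not given and no manifest next to {path}")
    return Trajectory(
        frames=frames,
        ph=float(ph),
        seed=meta.get("seed"),
        dt_ns=float(dt_ns if dt_ns is not None else meta.get("dt_ns", 1e-4)),
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_titration(path: str | Path) -> TitrationSeries:
    return TitrationSeries.from_frame(pd.read_csv(path))


def write_json(record: dict, path: str | Path | None) -> str:
    """Serialize a result record to JSON (stable key order as inserted)."""
    text = json.dumps(record, indent=2, allow_nan=False, default=_jsonify)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_manifest(record: dict, path: str | Path) -> None:
    write_json(record, path)


def _jsonify(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
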