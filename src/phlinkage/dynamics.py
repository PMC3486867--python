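"""Coarse-grained kinetic Monte Carlo of coupled protonation and conformation.

A discrete-time Markov chain over the four species of the linkage cycle
stands in for constant-pH MD.  Each step the chain may attempt two kinds of
Metropolis move:

* a protonation flip, attempted every ``mc_interval`` steps, with
  deprotonation free energy ΔG/kT = ln(10) * (pK_conf − pH) where pK_conf
  is the microscopic pKa of the current conformation — the same free-energy
  difference constant-pH MD feeds to its Metropolis test;
* a conformational flip (closed ↔ open) at fixed protonation, attempted
  with probability ``p_conf_attempt`` per step, with closed→open
  ΔG/kT = −ln K, K being K_H (protonated) or K_D (deprotonated).

Both moves satisfy detailed balance with respect to the four-state
equilibrium, so the stationary species frequencies reproduce the analytic
mass-balance populations at the chosen pH.  Rates are fictitious: only the
equilibrium constants are physical, and the default attempt frequencies are
picked so conformational relaxation is ~100× slower than protonation,
mimicking the look of real constant-pH trajectories (deprotonation first,
opening later).  Observables are emitted per frame from conformation-
conditional Gaussians whose parameters default to published closed/open
summary statistics (distances in Å, SASA in Å², truncated at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import TitrationSeries
from .linkage import ThermoCycle
from .trajectory import Trajectory

__all__ = [
    "KineticParams",
    "ObservableModel",
    "SimState",
    "protonation_acceptance",
    "conformation_acceptance",
    "protonation_step",
    "conformation_step",
    "simulate",
    "titration_experiment",
    "TitrationExperiment",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class KineticParams:
    """Chain length, attempt schedule and reproducibility knobs."""

    n_steps: int = 100_000
    mc_interval: int = 10
    p_conf_attempt: float = 0.01
    seed: int = 0
    burn_in: float = 0.1
    dt_ns: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.mc_interval < 1:
            raise ValueError("mc_interval must be >= 1")
        if not 0.0 <= self.p_conf_attempt <= 1.0:
            raise ValueError("p_conf_attempt must lie in [0, 1]")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in must lie in [0, 1)")


@dataclass(frozen=True)
class ObservableModel:
    """Conformation-conditional Gaussian emission parameters.

    Each entry is (closed_mean, closed_sd, open_mean, open_sd).  Defaults
    are the closed (pH 5.5) and open (pH 7.5) summary values for the two
    gating distances (Å) and the titratable-residue SASA (Å²); SASA draws
    are truncated at zero by resampling since the closed-state SD (4) is
    large relative to its mean (9).
    """

    d_asp30_leu130: tuple[float, float, float, float] = (3.5, 0.3, 8.0, 1.0)
    d_asp35_asp129: tuple[float, float, float, float] = (5.0, 1.0, 14.0, 3.0)
    sasa: tuple[float, float, float, float] = (9.0, 4.0, 40.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("d_asp30_leu130", "d_asp35_asp129", "sasa"):
            m_c, s_c, m_o, s_o = getattr(self, name)
            if s_c <= 0 or s_o <= 0:
                raise ValueError(f"{name}: standard deviations must be positive")
            if m_c < 0 or m_o < 0:
                raise ValueError(f"{name}: means must be non-negative")


@dataclass(frozen=True)
class SimState:
    """One of the four cycle species: (conformation, protonation)."""

    conformation: str = "closed"
    protonated: bool = True

    def __post_init__(self) -> None:
        if self.conformation not in ("closed", "open"):
            raise ValueError("conformation must be 'closed' or 'open'")

    @property
    def species(self) -> str:
        return {
            ("closed", True): "CH",
            ("closed", False): "C-",
            ("open", True): "OpH",
            ("open", False): "Op-",
        }[(self.conformation, self.protonated)]


def protonation_acceptance(protonated: bool, pk_conf: float, ph: float) -> float:
    """Metropolis acceptance probability for flipping the protonation state.

    Deprotonation costs ΔG/kT = ln10*(pK_conf − pH); protonation is the
    reverse move.  Within one conformation the stationary
    deprotonated:protonated ratio is therefore 10**(pH − pK_conf).
    """
    dg = LN10 * (pk_conf - ph) if protonated else LN10 * (ph - pk_conf)
    return min(1.0, math.exp(-dg))


def conformation_acceptance(conformation: str, k_conf: float) -> float:
    """Metropolis acceptance for a closed↔open flip at fixed protonation.

    ``k_conf`` is the open/closed equilibrium constant for the current
    protonation state (K_H protonated, K_D deprotonated); closed→open has
    ΔG/kT = −ln K, the reverse +ln K.
    """
    if k_conf <= 0:
        raise ValueError("equilibrium constant must be positive")
    return min(1.0, k_conf) if conformation == "closed" else min(1.0, 1.0 / k_conf)


def protonation_step(
    state: SimState, cycle: ThermoCycle, ph: float, rng: np.random.Generator
) -> SimState:
    """Attempt one Metropolis protonation flip."""
    pk_conf = cycle.pk_closed if state.conformation == "closed" else cycle.pk_open
    if rng.random() < protonation_acceptance(state.protonated, pk_conf, ph):
        return replace(state, protonated=not state.protonated)
    return state


def conformation_step(state: SimState, cycle: ThermoCycle, rng: np.random.Generator) -> SimState:
    """Attempt one Metropolis conformational flip at fixed protonation."""
    k_conf = cycle.kh if state.protonated else cycle.kd
    if rng.random() < conformation_acceptance(state.conformation, k_conf):
        flipped = "open" if state.conformation == "closed" else "closed"
        return replace(state, conformation=flipped)
    return state


def _state_arrays(
    cycle: ThermoCycle,
    ph: float,
    kin: KineticParams,
    rng: np.random.Generator,
    start: SimState,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the chain, returning per-step (open?, protonated?) int8 arrays.

    Uniforms are pre-drawn in fixed order (conf-attempt, conf-accept,
    prot-accept per step) so runs are bit-reproducible given the generator
    state regardless of which branches fire.
    """
    n = kin.n_steps
    u_att = rng.random(n)
    u_conf = rng.random(n)
    u_prot = rng.random(n)

    # acceptance table indexed by current state
    a_deprot = {  # protonated -> deprotonated
        "closed": protonation_acceptance(True, cycle.pk_closed, ph),
        "open": protonation_acceptance(True, cycle.pk_open, ph),
    }
    a_prot = {  # deprotonated -> protonated
        "closed": protonation_acceptance(False, cycle.pk_closed, ph),
        "open": protonation_acceptance(False, cycle.pk_open, ph),
    }
    a_c2o = {True: min(1.0, cycle.kh), False: min(1.0, cycle.kd)}
    a_o2c = {True: min(1.0, 1.0 / cycle.kh), False: min(1.0, 1.0 / cycle.kd)}

    is_open = start.conformation == "open"
    prot = start.protonated
    conf_out = np.empty(n, dtype=np.int8)
    prot_out = np.empty(n, dtype=np.int8)
    mc_interval = kin.mc_interval
    p_att = kin.p_conf_attempt
    for i in range(n):
        if i % mc_interval == 0:
            c = "open" if is_open else "closed"
            acc = a_deprot[c] if prot else a_prot[c]
            if u_prot[i] < acc:
                prot = not prot
        if u_att[i] < p_att:
            acc = a_o2c[prot] if is_open else a_c2o[prot]
            if u_conf[i] < acc:
                is_open = not is_open
        conf_out[i] = is_open
        prot_out[i] = prot
    return conf_out, prot_out


def _emit_observables(
    conf: np.ndarray, obs: ObservableModel, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw per-frame observables conditioned on the conformation sequence."""
    out: dict[str, np.ndarray] = {}
    is_open = conf.astype(bool)
    for name in ("d_asp30_leu130", "d_asp35_asp129", "sasa"):
        m_c, s_c, m_o, s_o = getattr(obs, name)
        mean = np.where(is_open, m_o, m_c)
        sd = np.where(is_open, s_o, s_c)
        x = mean + sd * rng.standard_normal(conf.size)
        # physical observables cannot be negative; resample the offenders
        neg = x < 0
        while np.any(neg):
            x[neg] = mean[neg] + sd[neg] * rng.standard_normal(int(neg.sum()))
            neg = x < 0
        out[name] = x
    return out


def simulate(
    cycle: ThermoCycle,
    ph: float,
    kin: KineticParams | None = None,
    obs: ObservableModel | None = None,
    start: SimState | None = None,
) -> Trajectory:
    """Generate one synthetic constant-pH-style trajectory.

    Runs the coupled protonation/conformation chain for ``kin.n_steps``
    steps at solvent ``ph``, recording every step as a frame with
    conformation-conditional observables.  Fully reproducible given
    ``kin.seed``; the default start is closed-protonated, the species a
    low-pH-stable protein begins in.
    """
    kin = kin or KineticParams()
    obs = obs or ObservableModel()
    start = start or SimState()
    rng = np.random.default_rng(kin.seed)
    conf, prot = _state_arrays(cycle, ph, kin, rng, start)
    observables = _emit_observables(conf, obs, rng)
    frames = pd.DataFrame(
        {
            "time_ns": np.arange(kin.n_steps, dtype=float) * kin.dt_ns,
            "conformation": pd.Categorical.from_codes(
                conf, categories=["closed", "open"]
            ),
            "protonated": prot,
            **observables,
        }
    )
    return Trajectory(frames=frames, ph=ph, seed=kin.seed, dt_ns=kin.dt_ns)


def species_counts(traj: Trajectory, burn_in: float = 0.1) -> dict[str, int]:
    """Post-burn-in frame counts of the four species CH, C-, OpH, Op-."""
    df = traj.frames.iloc[int(burn_in * len(traj.frames)):]
    is_open = (df["conformation"] == "open").to_numpy()
    prot = df["protonated"].to_numpy(bool)
    return {
        "CH": int((~is_open & prot).sum()),
        "C-": int((~is_open & ~prot).sum()),
        "OpH": int((is_open & prot).sum()),
        "Op-": int((is_open & ~prot).sum()),
    }


@dataclass
class TitrationExperiment:
    """Output of a multi-pH simulation campaign."""

    overall: TitrationSeries
    closed: TitrationSeries
    open: TitrationSeries
    trajectories: list[Trajectory] = field(default_factory=list)


def titration_experiment(
    cycle: ThermoCycle,
    ph_grid: list[float] | np.ndarray,
    kin: KineticParams | None = None,
    obs: ObservableModel | None = None,
    keep_trajectories: bool = True,
) -> TitrationExperiment:
    """Independent simulations across a pH grid, tallied for pKa estimation.

    Each pH runs with seed ``kin.seed + index`` so individual points can be
    reproduced in isolation.  Post-burn-in protonated/total counts are
    returned overall and partitioned by conformation — the partitioned
    tables feed conformation-specific microscopic pKa fits, while the
    overall table titrates the whole coupled system and its midpoint is the
    apparent, not a microscopic, pKa.
    """
    kin = kin or KineticParams()
    obs = obs or ObservableModel()
    grid = np.asarray(ph_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("pH grid must be non-empty")
    rows = {"overall": [], "closed": [], "open": []}
    trajectories = []
    for i, ph in enumerate(grid):
        traj = simulate(cycle, float(ph), replace(kin, seed=kin.seed + i), obs)
        df = traj.frames.iloc[int(kin.burn_in * len(traj.frames)):]
        prot = df["protonated"].to_numpy(bool)
        is_open = (df["conformation"] == "open").to_numpy()
        rows["overall"].append((ph, int(prot.sum()), len(df)))
        rows["closed"].append((ph, int(prot[~is_open].sum()), int((~is_open).sum())))
        rows["open"].append((ph, int(prot[is_open].sum()), int(is_open.sum())))
        if keep_trajectories:
            trajectories.append(traj)

    def build(key: str, conformation: str | None) -> TitrationSeries:
        pts = [(p, k, n) for p, k, n in rows[key] if n > 0]
        return TitrationSeries(
            ph=np.array([p for p, _, _ in pts]),
            n_protonated=np.array([k for _, k, _ in pts]),
            n_total=np.array([n for _, _, n in pts]),
            conformation=conformation,
        )

    return TitrationExperiment(
        overall=build("overall", None),
        closed=build("closed", "closed"),
        open=build("open", "open"),
        trajectories=trajectories,
    )
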