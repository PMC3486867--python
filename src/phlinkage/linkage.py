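"""Closed-form four-state proton-linkage model.

A protein with two conformations (closed, open) and one titratable residue
occupies four species: closed-protonated (CH), closed-deprotonated (C-),
open-protonated (OpH) and open-deprotonated (Op-).  Vertical equilibria are
acid dissociations governed by the conformation-specific ("microscopic")
pKa values ``pk_closed`` and ``pk_open``; horizontal equilibria are the
conformational constants K_H = [OpH]/[CH] (protonated) and
K_D = [Op-]/[C-] (deprotonated).  The cycle closes, so only three of the
four constants are free:

    K_H = K_D * 10**(pk_open - pk_closed)

Given the cycle, species mole fractions follow from mass balance at any pH,
an experimental observable that differs between the conformations traces a
sigmoid in pH, and the inflection point of that sigmoid is the single
"apparent" pKa an experiment reports:

    pK_app = pk_closed + log10((1 + K_H) / (1 + K_D))

which always lies between the two microscopic values when K_H <= 1 <= K_D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ThermoCycle",
    "StateDistribution",
    "SignalModel",
    "TransitionUndefinedError",
    "derive_kh",
    "populations",
    "population_curve",
    "signal",
    "apparent_pka",
    "apparent_pka_numeric",
    "kd_scan",
    "optimal_kd",
    "valid_kd_range",
]

LN10 = np.log(10.0)

#: Reference parameters: microscopic pKa 8.5 (closed) / 4.3 (open), K_D = 100.
REFERENCE_PK_CLOSED = 8.5
REFERENCE_PK_OPEN = 4.3
REFERENCE_KD = 100.0


class TransitionUndefinedError(ValueError):
    """The open-fraction limits coincide: no conformational transition exists."""


def derive_kh(pk_closed: float, pk_open: float, kd: float) -> float:
    """Conformational constant K_H = [OpH]/[CH] from cycle closure.

    The free-energy changes around the four-state loop must sum to zero,
    which fixes K_H = K_D * 10**(pk_open - pk_closed).

    Parameters
    ----------
    pk_closed, pk_open : float
        Microscopic pKa of the titratable residue in each conformation.
    kd : float
        Conformational constant with the residue deprotonated, [Op-]/[C-].
    """
    if not (np.isfinite(pk_closed) and np.isfinite(pk_open)):
        raise ValueError("pK values must be finite")
    if not (np.isfinite(kd) and kd > 0):
        raise ValueError(f"K_D must be positive and finite, got {kd}")
    return kd * 10.0 ** (pk_open - pk_closed)


@dataclass(frozen=True)
class ThermoCycle:
    """Four-state thermodynamic cycle parameters.

    ``kh`` is derived from the other three constants by cycle closure and
    cannot be set independently.
    """

    pk_closed: float = REFERENCE_PK_CLOSED
    pk_open: float = REFERENCE_PK_OPEN
    kd: float = REFERENCE_KD
    kh: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kh", derive_kh(self.pk_closed, self.pk_open, self.kd))

    def log_weights(self, ph: float | np.ndarray) -> np.ndarray:
        """Natural-log Boltzmann weights of (CH, C-, OpH, Op-) relative to CH.

        With u = 10**(pH - pk_closed) the unnormalized weights are
        (1, u, K_H, K_D*u).  Returned in log space so extreme pH values
        never overflow.
        """
        lu = LN10 * (np.asarray(ph, dtype=float) - self.pk_closed)
        zero = np.zeros_like(lu)
        return np.stack(
            [zero, lu, zero + np.log(self.kh), lu + np.log(self.kd)], axis=-1
        )


@dataclass(frozen=True)
class StateDistribution:
    """Mole fractions of the four species at one pH."""

    ph: float
    x_ch: float
    x_c_minus: float
    x_oph: float
    x_op_minus: float

    def __post_init__(self) -> None:
        fracs = (self.x_ch, self.x_c_minus, self.x_oph, self.x_op_minus)
        if any(not (0.0 <= x <= 1.0) for x in fracs):
            raise ValueError(f"mole fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-10:
            raise ValueError(f"mole fractions must sum to 1, got {sum(fracs)!r}")

    @property
    def x_closed(self) -> float:
        """Total closed fraction, CH + C-."""
        return self.x_ch + self.x_c_minus

    @property
    def x_open(self) -> float:
        """Total open fraction, OpH + Op-."""
        return self.x_oph + self.x_op_minus

    def as_dict(self) -> dict[str, float]:
        return {
            "pH": self.ph,
            "x_CH": self.x_ch,
            "x_Cminus": self.x_c_minus,
            "x_OpH": self.x_oph,
            "x_Opminus": self.x_op_minus,
        }


@dataclass(frozen=True)
class SignalModel:
    """Limiting observable values in each conformation.

    ``alpha`` is the signal when the ensemble is fully closed, ``beta`` when
    fully open (e.g. the NO dissociation constant plateaus of a nitrophorin
    titration: alpha = 0.03, beta = 0.55).
    """

    alpha: float = 0.03
    beta: float = 0.55

    def __post_init__(self) -> None:
        if self.alpha == self.beta:
            raise ValueError("alpha must differ from beta: equal limits carry no conformational signal")


def populations(cycle: ThermoCycle, ph: float) -> StateDistribution:
    """Equilibrium mole fractions of CH, C-, OpH, Op- at ``ph``.

    Mass balance over the cycle gives unnormalized weights
    (1, u, K_H, K_D*u) with u = 10**(pH - pk_closed); fractions are weights
    over their sum, evaluated in log space so that arbitrarily extreme pH
    is overflow-safe.
    """
    if not np.isfinite(ph):
        raise ValueError("pH must be finite")
    lw = cycle.log_weights(ph)
    x = np.exp(lw - logsumexp(lw))
    return StateDistribution(ph=ph, x_ch=x[0], x_c_minus=x[1], x_oph=x[2], x_op_minus=x[3])


def population_curve(cycle: ThermoCycle, ph_grid: Sequence[float]) -> list[StateDistribution]:
    """``populations`` over a strictly increasing pH grid."""
    grid = np.asarray(ph_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("pH grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("pH grid must be strictly increasing")
    return [populations(cycle, ph) for ph in grid]


def open_fraction(cycle: ThermoCycle, ph: float | np.ndarray) -> float | np.ndarray:
    """Total open mole fraction OpH + Op- (a logistic in pH)."""
    lw = cycle.log_weights(ph)
    return np.exp(logsumexp(lw[..., 2:], axis=-1) - logsumexp(lw, axis=-1))


def signal(cycle: ThermoCycle, sig: SignalModel, ph: float | np.ndarray) -> float | np.ndarray:
    """Ensemble-averaged observable alpha*x_closed + beta*x_open."""
    f_open = open_fraction(cycle, ph)
    return sig.alpha * (1.0 - f_open) + sig.beta * f_open


def _check_transition(cycle: ThermoCycle) -> None:
    # open-fraction plateaus: K_H/(1+K_H) at low pH, K_D/(1+K_D) at high pH
    lo = cycle.kh / (1.0 + cycle.kh)
    hi = cycle.kd / (1.0 + cycle.kd)
    if abs(hi - lo) <= 1e-9:
        raise TransitionUndefinedError(
            "open-fraction limits coincide (K_H == K_D); no pH-driven transition"
        )


def apparent_pka(cycle: ThermoCycle) -> float:
    """Apparent (macroscopic) pKa of the closed-to-open transition.

    The open fraction is a logistic in pH with midpoint at
    u = (1 + K_H)/(1 + K_D), so the inflection of any affine signal is

        pK_app = pk_closed + log10((1 + K_H) / (1 + K_D)).

    For K_H <= 1 <= K_D this is bounded by the two microscopic pKa values.
    The fully symmetric cycle (pk_closed == pk_open, hence K_H == K_D) is
    handled by continuity: the two microscopic pKa values coincide and the
    apparent pKa equals them, even though the conformational populations
    then carry no pH signal.
    """
    if cycle.pk_closed == cycle.pk_open:
        return cycle.pk_closed
    _check_transition(cycle)
    return cycle.pk_closed + np.log10((1.0 + cycle.kh) / (1.0 + cycle.kd))


def apparent_pka_numeric(
    cycle: ThermoCycle,
    sig: SignalModel | None = None,
    tol: float = 1e-6,
) -> float:
    """Apparent pKa located numerically as the signal-curve inflection.

    Scans [pk_open - 4, pk_closed + 4] for the maximum of |dsignal/dpH| —
    the sigmoid midpoint, where the curvature is well-scaled — then brackets
    the sign change of the second derivative around it and bisects to
    ``tol``.  Serves as the independent oracle for the closed form in
    :func:`apparent_pka`.
    """
    _check_transition(cycle)
    if sig is None:
        sig = SignalModel()
    # h large enough that centred differences stay above roundoff even for
    # low-amplitude transitions (plateau gap ~1e-6); the O(h^2) truncation
    # shift of the root is ~1e-4 pH units, inside the 1e-3 agreement band
    h = 1e-2

    def d2(ph: float) -> float:
        s = signal(cycle, sig, np.array([ph - h, ph, ph + h]))
        return (s[0] - 2.0 * s[1] + s[2]) / (h * h)

    lo = min(cycle.pk_open, cycle.pk_closed) - 4.0
    hi = max(cycle.pk_open, cycle.pk_closed) + 4.0
    grid = np.linspace(lo, hi, 1601)
    slope = np.abs(signal(cycle, sig, grid + h) - signal(cycle, sig, grid - h))
    peak = int(np.argmax(slope))
    a = grid[max(peak - 1, 0)]
    b = grid[min(peak + 1, grid.size - 1)]
    fa = d2(a)
    if fa * d2(b) > 0:
        raise TransitionUndefinedError("no inflection point found in bracket")
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = d2(m)
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def kd_scan(
    pk_closed: float,
    pk_open: float,
    kd_grid: Sequence[float],
    ph_low: float = 5.5,
    ph_high: float = 7.5,
) -> pd.DataFrame:
    """Scan K_D: apparent pKa and the two functional mole fractions.

    One row per K_D with columns ``kd``, ``kh``, ``apparent_pka``,
    ``x_ch_low`` (closed-protonated fraction at ``ph_low``) and
    ``x_op_minus_high`` (open-deprotonated fraction at ``ph_high``) —
    the two quantities a pH-switched carrier protein must maximize.
    """
    kds = np.asarray(kd_grid, dtype=float)
    if kds.size == 0 or np.any(kds <= 0) or not np.all(np.isfinite(kds)):
        raise ValueError("K_D grid entries must be positive and finite")
    rows = []
    for kd in kds:
        cyc = ThermoCycle(pk_closed, pk_open, kd)
        rows.append(
            {
                "kd": kd,
                "kh": cyc.kh,
                "apparent_pka": apparent_pka(cyc),
                "x_ch_low": populations(cyc, ph_low).x_ch,
                "x_op_minus_high": populations(cyc, ph_high).x_op_minus,
            }
        )
    return pd.DataFrame(rows)


def optimal_kd(
    pk_closed: float = REFERENCE_PK_CLOSED,
    pk_open: float = REFERENCE_PK_OPEN,
    ph_low: float = 5.5,
    ph_high: float = 7.5,
    tol: float = 1e-4,
) -> float:
    """K_D maximizing min(x_CH at ph_low, x_Op- at ph_high).

    x_CH(ph_low) decreases and x_Op-(ph_high) increases strictly with K_D,
    so the maximin sits at their unique crossing; solved by bisection on
    log10 K_D in [-2, 6] to ``tol`` in log10 units.
    """
    if not ph_low < ph_high:
        raise ValueError("ph_low must be below ph_high")

    def gap(log_kd: float) -> float:
        cyc = ThermoCycle(pk_closed, pk_open, 10.0 ** log_kd)
        return populations(cyc, ph_low).x_ch - populations(cyc, ph_high).x_op_minus

    a, b = -2.0, 6.0
    fa = gap(a)
    while b - a > tol:
        m = 0.5 * (a + b)
        if fa * gap(m) <= 0:
            b = m
        else:
            a = m
            fa = gap(a)
    return 10.0 ** (0.5 * (a + b))


def valid_kd_range(
    pk_closed: float = REFERENCE_PK_CLOSED,
    pk_open: float = REFERENCE_PK_OPEN,
    threshold: float = 0.10,
    mode: str = "asymptotic",
    ph_low: float | None = None,
    ph_high: float | None = None,
) -> tuple[float, float]:
    """K_D interval keeping both off-pathway species below ``threshold``.

    Outside this interval the model predicts a significant population of a
    species the functional picture forbids: C- at high pH (K_D too small)
    or OpH at low pH (K_D too large).

    In ``asymptotic`` mode the limiting fractions have closed forms —
    x_C- -> 1/(1 + K_D) as pH -> +inf and x_OpH -> K_H/(1 + K_H) as
    pH -> -inf — giving kd_min = 1/threshold - 1 and
    kd_max = threshold/(1 - threshold) * 10**(pk_closed - pk_open).
    In ``fixed`` mode the fractions are evaluated at ``ph_high`` / ``ph_low``
    and the bounds located by bisection.
    """
    if not 0.0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    if mode == "asymptotic":
        kd_min = 1.0 / threshold - 1.0
        kh_max = threshold / (1.0 - threshold)
        kd_max = kh_max * 10.0 ** (pk_closed - pk_open)
        return kd_min, kd_max
    if mode != "fixed":
        raise ValueError(f"mode must be 'asymptotic' or 'fixed', got {mode!r}")
    if ph_low is None or ph_high is None:
        raise ValueError("fixed mode requires ph_low and ph_high")

    def bisect_root(f, a: float, b: float) -> float:
        fa = f(a)
        if fa * f(b) > 0:
            # fraction never reaches the threshold inside the bracket
            return 10.0 ** (a if abs(fa) < abs(f(b)) else b)
        while b - a > 1e-6:
            m = 0.5 * (a + b)
            if fa * f(m) <= 0:
                b = m
            else:
                a = m
                fa = f(a)
        return 10.0 ** (0.5 * (a + b))

    # x_C-(ph_high) decreases with K_D: kd_min is where it drops to threshold
    kd_min = bisect_root(
        lambda lk: populations(ThermoCycle(pk_closed, pk_open, 10.0 ** lk), ph_high).x_c_minus
        - threshold,
        -6.0,
        8.0,
    )
    # x_OpH(ph_low) increases with K_D: kd_max is where it reaches threshold
    kd_max = bisect_root(
        lambda lk: populations(ThermoCycle(pk_closed, pk_open, 10.0 ** lk), ph_low).x_oph
        - threshold,
        -6.0,
        8.0,
    )
    return kd_min, kd_max
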