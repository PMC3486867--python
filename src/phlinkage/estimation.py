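"""pKa and trajectory statistics from constant-pH-style time series.

Protonation-state time series at known solvent pH carry the residue's pKa
through the Henderson–Hasselbalch relation: assuming ergodic sampling, the
fraction of frames spent protonated, f, satisfies

    pKa = pH + log10(f / (1 - f)).

This module inverts single-pH counts (with binomial error propagation and
one-sided censoring when f hits 0 or 1), fits multi-pH titration tables by
binomial maximum likelihood with an optional Hill coefficient, partitions
trajectories by conformation to recover conformation-specific microscopic
pKa values, and provides the trajectory analytics used to read off
conformational transitions: trailing running averages, windowed pKa traces,
summary statistics, midpoint-crossing transition detection, and a
moving-block bootstrap for autocorrelated series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_expit

from .trajectory import Trajectory

__all__ = [
    "TitrationSeries",
    "PkaEstimate",
    "pka_from_counts",
    "fit_titration",
    "conditional_pka",
    "running_pka",
    "running_average",
    "summarize_observable",
    "detect_transition",
    "bootstrap_ci",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class TitrationSeries:
    """Per-pH protonated/total frame counts, optionally conformation-tagged."""

    ph: np.ndarray
    n_protonated: np.ndarray
    n_total: np.ndarray
    conformation: str | None = None

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        npr = np.asarray(self.n_protonated, dtype=np.int64)
        ntot = np.asarray(self.n_total, dtype=np.int64)
        if not (ph.shape == npr.shape == ntot.shape):
            raise ValueError("ph, n_protonated and n_total must have equal length")
        if len(np.unique(ph)) != ph.size:
            raise ValueError("pH values must be distinct")
        if np.any(ntot <= 0):
            raise ValueError("n_total must be positive at every point")
        if np.any(npr < 0) or np.any(npr > ntot):
            raise ValueError("need 0 <= n_protonated <= n_total")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "n_protonated", npr)
        object.__setattr__(self, "n_total", ntot)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pH": self.ph, "n_prot": self.n_protonated, "n_total": self.n_total}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, conformation: str | None = None) -> "TitrationSeries":
        return cls(
            ph=df["pH"].to_numpy(float),
            n_protonated=df["n_prot"].to_numpy(np.int64),
            n_total=df["n_total"].to_numpy(np.int64),
            conformation=conformation,
        )


@dataclass(frozen=True)
class PkaEstimate:
    """A pKa estimate with uncertainty, or a one-sided censored bound.

    When every frame is (de)protonated the data only bound the pKa relative
    to the solvent pH; ``censored`` is then ``">"`` or ``"<"`` and ``bound``
    holds the pH, while ``pka`` is NaN.  Estimates are never infinite.
    """

    pka: float
    hill: float = 1.0
    stderr: float | None = None
    ci: tuple[float, float] | None = None
    n_samples: int = 0
    method: str = "single-pH inversion"
    censored: str | None = None
    bound: float | None = None

    def __post_init__(self) -> None:
        if self.censored not in (None, "<", ">"):
            raise ValueError("censored must be None, '<' or '>'")
        if self.censored is None:
            if not np.isfinite(self.pka):
                raise ValueError("uncensored estimate must be finite")
            if self.ci is not None and not (self.ci[0] <= self.pka <= self.ci[1]):
                raise ValueError("confidence interval must contain the point estimate")

    @property
    def is_censored(self) -> bool:
        return self.censored is not None

    def __str__(self) -> str:
        if self.is_censored:
            return f"pKa {self.censored} {self.bound:.2f} (censored, n={self.n_samples})"
        s = f"pKa = {self.pka:.2f}"
        if self.stderr is not None:
            s += f" ± {self.stderr:.2f}"
        return s

    def as_dict(self) -> dict:
        return {
            "pka": None if self.is_censored else self.pka,
            "hill": self.hill,
            "stderr": self.stderr,
            "ci": list(self.ci) if self.ci is not None else None,
            "n_samples": int(self.n_samples),
            "method": self.method,
            "censored": self.censored,
            "bound": self.bound,
        }


def pka_from_counts(ph: float, n_protonated: int, n_total: int) -> PkaEstimate:
    """Henderson–Hasselbalch inversion of a protonated-frame count.

    The standard error propagates the binomial error of f through the
    log-odds: se(pKa) = 1 / (ln10 * sqrt(n * f * (1 - f))), an i.i.d.-frames
    approximation (see :func:`bootstrap_ci` for autocorrelated series).
    f = 0 or 1 yields a one-sided censored estimate.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_protonated <= n_total:
        raise ValueError("need 0 <= n_protonated <= n_total")
    if n_protonated == 0:
        return PkaEstimate(pka=np.nan, censored="<", bound=ph, n_samples=n_total)
    if n_protonated == n_total:
        return PkaEstimate(pka=np.nan, censored=">", bound=ph, n_samples=n_total)
    f = n_protonated / n_total
    pka = ph + np.log10(f / (1.0 - f))
    stderr = 1.0 / (LN10 * np.sqrt(n_total * f * (1.0 - f)))
    return PkaEstimate(
        pka=pka,
        stderr=stderr,
        ci=(pka - 1.959964 * stderr, pka + 1.959964 * stderr),
        n_samples=n_total,
    )


def _titration_nll(series: TitrationSeries) -> Callable[[np.ndarray], float]:
    ph, k, n = series.ph, series.n_protonated, series.n_total

    def nll(theta: np.ndarray) -> float:
        pka, hill = theta[0], theta[1] if theta.size > 1 else 1.0
        # protonated fraction f = 1 / (1 + 10**(hill*(pH - pKa))) = expit(ln10*hill*(pKa - pH))
        z = LN10 * hill * (pka - ph)
        return -float(np.sum(k * log_expit(z) + (n - k) * log_expit(-z)))

    return nll


def _curvature_stderr(nll: Callable[[np.ndarray], float], theta: np.ndarray) -> np.ndarray:
    """Standard errors from the inverse of a central-difference Hessian."""
    p = theta.size
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.eye(p)[i] * h[i]
            ej = np.eye(p)[j] * h[j]
            hess[i, j] = hess[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej) - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def fit_titration(series: TitrationSeries, fix_hill: bool = True) -> PkaEstimate:
    """Binomial maximum-likelihood fit of a titration table.

    Fits f(pH) = 1 / (1 + 10**(n_H * (pH - pKa))) to the protonated counts.
    With ``fix_hill`` the Hill coefficient n_H is pinned to 1 (a single
    ideal site); freeing it is a diagnostic for cooperative or heterogeneous
    titration.  Standard errors come from the likelihood curvature.
    """
    informative = (series.n_protonated > 0) & (series.n_protonated < series.n_total)
    needed = 2 if fix_hill else 3
    if int(informative.sum()) < needed:
        raise ValueError(
            f"titration fit needs >= {needed} points with 0 < f < 1, "
            f"got {int(informative.sum())}: all other points only bound the pKa"
        )
    # crude start: average single-point inversions over informative points
    f = series.n_protonated[informative] / series.n_total[informative]
    x0_pka = float(np.mean(series.ph[informative] + np.log10(f / (1.0 - f))))
    nll = _titration_nll(series)
    if fix_hill:
        theta0 = np.array([x0_pka])
        res = minimize(lambda t: nll(np.array([t[0], 1.0])), theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        theta = np.array([res.x[0], 1.0])
        se = _curvature_stderr(lambda t: nll(np.array([t[0], 1.0])), res.x)
        stderr, hill = float(se[0]), 1.0
    else:
        theta0 = np.array([x0_pka, 1.0])
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        theta = res.x
        se = _curvature_stderr(nll, theta)
        stderr, hill = float(se[0]), float(theta[1])
    pka = float(theta[0])
    return PkaEstimate(
        pka=pka,
        hill=hill,
        stderr=stderr,
        ci=(pka - 1.959964 * stderr, pka + 1.959964 * stderr) if np.isfinite(stderr) else None,
        n_samples=int(series.n_total.sum()),
        method="multi-pH fit",
    )


def conditional_pka(
    trajectories: Trajectory | Sequence[Trajectory],
    burn_in: float = 0.1,
) -> tuple[PkaEstimate, PkaEstimate]:
    """Conformation-conditioned microscopic pKa estimates.

    Pools one or more trajectories recorded at the same solvent pH, drops
    the first ``burn_in`` fraction of each as equilibration, partitions the
    remaining frames by conformation label, and inverts each partition's
    protonated fraction.  Returns (closed-conditioned, open-conditioned);
    an empty partition yields a fully censored placeholder.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("need at least one trajectory")
    phs = {t.ph for t in trajectories}
    if len(phs) != 1:
        raise ValueError(f"trajectories must share one pH, got {sorted(phs)}")
    ph = phs.pop()
    counts = {"closed": [0, 0], "open": [0, 0]}
    for traj in trajectories:
        df = traj.frames.iloc[int(burn_in * len(traj.frames)):]
        for conf in ("closed", "open"):
            sel = df["conformation"] == conf
            counts[conf][0] += int(df.loc[sel, "protonated"].sum())
            counts[conf][1] += int(sel.sum())
    out = []
    for conf in ("closed", "open"):
        n_prot, n_tot = counts[conf]
        if n_tot == 0:
            out.append(PkaEstimate(pka=np.nan, censored="<", bound=ph, n_samples=0,
                                   method=f"single-pH inversion ({conf}, empty)"))
        else:
            est = pka_from_counts(ph, n_prot, n_tot)
            out.append(replace(est, method=f"single-pH inversion ({conf})"))
    return out[0], out[1]


def running_average(series: Sequence[float], window: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing mean with expanding-mean fill-in for the first window-1 frames.

    Returns ``(smoothed, filled)`` of the input length; ``filled`` marks
    entries computed from fewer than ``window`` frames.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = (
        pd.Series(x).rolling(window, min_periods=1).mean().to_numpy()
    )
    filled = np.arange(x.size) < window - 1
    return smoothed, filled


def running_pka(traj: Trajectory, window: int) -> pd.DataFrame:
    """Trailing-window pKa trace from a trajectory's protonation series.

    Converts the protonated count in each trailing window of ``window``
    frames via Henderson–Hasselbalch at the trajectory pH.  Returns a frame
    with columns ``time_ns``, ``pka`` (NaN while the window is unfilled or
    the window is censored) and ``censored`` ('<', '>' or None).
    """
    if window < 10:
        raise ValueError("window must be >= 10 frames")
    n = len(traj.frames)
    if window > n:
        raise ValueError(f"window ({window}) exceeds trajectory length ({n})")
    prot = traj.frames["protonated"].to_numpy(float)
    counts = pd.Series(prot).rolling(window).sum().to_numpy()
    pka = np.full(n, np.nan)
    censored = np.full(n, None, dtype=object)
    valid = ~np.isnan(counts)
    k = counts[valid]
    f = k / window
    interior = (k > 0) & (k < window)
    idx = np.nonzero(valid)[0]
    pka[idx[interior]] = traj.ph + np.log10(f[interior] / (1.0 - f[interior]))
    censored[idx[k == 0]] = "<"
    censored[idx[k == window]] = ">"
    return pd.DataFrame(
        {"time_ns": traj.frames["time_ns"].to_numpy(), "pka": pka, "censored": censored}
    )


def summarize_observable(series: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of an observable series."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 frames to summarize")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def detect_transition(
    series: Sequence[float],
    ref_a: tuple[float, float],
    ref_b: tuple[float, float],
    persistence: int = 50,
    window: int = 1,
) -> int | None:
    """First persistent crossing from the ``ref_a`` basin to the ``ref_b`` basin.

    Smooths the series with a trailing ``window``-frame average, then returns
    the first index whose smoothed value lies on the ``ref_b`` side of the
    midpoint between the two reference means and stays there for at least
    ``persistence`` frames; ``None`` if no such crossing occurs.  Smoothing
    delays the reported index by up to ``window - 1`` frames.
    """
    mean_a, sd_a = ref_a
    mean_b, sd_b = ref_b
    if abs(mean_a - mean_b) <= sd_a + sd_b:
        raise ValueError("reference states overlap: means must differ by more than the summed SDs")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    smoothed, _ = running_average(series, window)
    midpoint = 0.5 * (mean_a + mean_b)
    far = (smoothed - midpoint) * np.sign(mean_b - midpoint) > 0
    n = far.size
    if n < persistence:
        return None
    # first index i such that far[i:i+persistence] is all True
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if far[i] else 0
        far[i] = run >= persistence
    hits = np.nonzero(far)[0]
    return int(hits[0]) if hits.size else None


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": np.mean,
    "std": lambda x: np.std(x, ddof=1),
    "median": np.median,
}


def bootstrap_ci(
    series: Sequence[float],
    statistic: str | Callable[[np.ndarray], float] = "mean",
    n_boot: int = 1000,
    block_length: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Moving-block bootstrap 95% percentile interval.

    Resamples overlapping blocks of ``block_length`` consecutive frames with
    replacement to respect serial correlation, recomputes ``statistic`` on
    each resample and returns the (2.5, 97.5) percentiles.  ``block_length=1``
    reduces to the ordinary i.i.d. bootstrap.
    """
    x = np.asarray(series, dtype=float)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if block_length < 1 or block_length > x.size:
        raise ValueError("block_length must be in [1, len(series)]")
    stat = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng(seed)
    n = x.size
    n_blocks = int(np.ceil(n / block_length))
    starts = rng.integers(0, n - block_length + 1, size=(n_boot, n_blocks))
    offsets = np.arange(block_length)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        sample = x[(starts[b][:, None] + offsets).ravel()[:n]]
        vals[b] = stat(sample)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)
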