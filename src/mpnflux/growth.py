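"""Growth-curve kinetics: specific growth rates, logistic fits, cell yields.

Batch cultures of *Prochlorococcus* grown on a single phosphorus source
follow logistic dynamics

    N(t) = K * N0 * exp(mu * t) / (K + N0 * (exp(mu * t) - 1))

with N0 the inoculum density (cells ml^-1), K the carrying capacity
(maximum cell yield, cells ml^-1) and mu the maximum specific growth
rate (d^-1).  Two estimators are provided: a full three-parameter
logistic least-squares fit on ln-density, and the classical
"linear interval" estimator — the OLS slope of ln(density) vs time over
the window spanning exponential growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "RateEstimate",
    "logistic_density",
    "fit_logistic",
    "exponential_growth_rate",
    "max_yield",
    "read_growth_csv",
    "write_growth_csv",
    "fit_all",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Cell-density time series for one culture replicate on one P substrate.

    time is in days (strictly increasing, >= 0); density in cells ml^-1
    (finite, > 0).
    """

    substrate: str
    replicate: str
    time: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        n = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "density", n)
        if t.ndim != 1 or n.shape != t.shape:
            raise ValueError("time and density must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise ValueError("time must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(n)) or np.any(n <= 0):
            raise ValueError("densities must be finite and positive")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class LogisticFit:
    """Result of a 3-parameter logistic fit on ln-density."""

    mu: float                 # d^-1
    K: float                  # cells ml^-1
    N0: float                 # cells ml^-1
    rss: float                # residual sum of squares on ln-density
    converged: bool

    def predict(self, time: np.ndarray) -> np.ndarray:
        return logistic_density(np.asarray(time, dtype=float), self.mu, self.K, self.N0)


@dataclass(frozen=True)
class RateEstimate:
    """Specific growth rate from the linear interval of exponential growth."""

    mu: float                           # d^-1
    window: tuple[int, int]             # (start, end) indices, inclusive
    r2: float                           # of the ln-linear fit; nan if undefined
    n_points: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def logistic_density(t: np.ndarray, mu: float, K: float, N0: float) -> np.ndarray:
    """Logistic growth N(t); numerically safe for large mu*t."""
    t = np.asarray(t, dtype=float)
    if mu == 0.0:
        return np.full_like(t, float(N0))
    # N(t) = K / (1 + (K/N0 - 1) * exp(-mu t))   (overflow-safe form)
    return K / (1.0 + (K / N0 - 1.0) * np.exp(-mu * t))


def exponential_growth_rate(
    curve: GrowthCurve,
    min_window: int = 4,
    cap_fraction: float = 0.5,
) -> RateEstimate:
    """Growth rate as the OLS slope of ln(density) vs time over the linear interval.

    Window selection: scan all contiguous windows of at least `min_window`
    points (or the whole series when shorter) whose maximum density does not
    exceed `cap_fraction` of the highest observed density, and keep the window
    with the highest r^2; ties are broken by longer window, then earlier
    start.  If no window satisfies the density cap (e.g. a pure exponential
    series), the cap is dropped.  This excludes stationary-phase points while
    staying deterministic.
    """
    n = len(curve)
    if n < 3:
        raise ValueError("need at least 3 points to estimate a growth rate")
    t, dens = curve.time, curve.density
    ln_n = np.log(dens)

    if np.allclose(dens, dens[0]):
        return RateEstimate(mu=0.0, window=(0, n - 1), r2=float("nan"),
                            n_points=n, flags=("constant_density",))

    w = min(min_window, n)
    cap = cap_fraction * dens.max()

    def candidates(use_cap: bool) -> list[tuple[int, int]]:
        out = []
        for i in range(n):
            for j in range(i + w - 1, n):
                if use_cap and dens[i:j + 1].max() > cap:
                    continue
                out.append((i, j))
        return out

    wins = candidates(True)
    flags: list[str] = []
    if not wins:
        wins = candidates(False)
        flags.append("density_cap_dropped")

    best: tuple[float, int, int, tuple[int, int]] | None = None
    best_fit = None
    for (i, j) in wins:
        res = stats.linregress(t[i:j + 1], ln_n[i:j + 1])
        r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 0.0
        # rank: r2 (rounded against float noise), window length, earlier start
        key = (np.round(r2, 12), j - i, -i, (i, j))
        if best is None or key > best:
            best, best_fit = key, res
    i, j = best[3]
    return RateEstimate(mu=float(best_fit.slope), window=(i, j),
                        r2=float(best_fit.rvalue ** 2), n_points=j - i + 1,
                        flags=tuple(flags))


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares fit of the 3-parameter logistic model on ln-density.

    Fitting on the log scale matches the multiplicative error structure of
    cell counts.  Initialisation: K0 = 1.05 x max density, N0_0 = first
    density, mu0 = the exponential-window slope.  On optimizer failure the
    result carries converged=False rather than silently returning garbage.
    """
    if len(curve) < 4:
        raise ValueError("logistic fit needs at least 4 points")
    t, dens = curve.time, curve.density
    ln_n = np.log(dens)

    if np.allclose(dens, dens[0]):
        return LogisticFit(mu=0.0, K=float(dens.max()), N0=float(dens[0]),
                           rss=0.0, converged=True)

    mu0 = max(exponential_growth_rate(curve).mu, 1e-3)
    K0 = 1.05 * float(dens.max())
    N00 = float(dens[0])

    def resid(theta: np.ndarray) -> np.ndarray:
        mu, ln_k, ln_n0 = theta
        pred = logistic_density(t, mu, np.exp(ln_k), np.exp(ln_n0))
        return np.log(pred) - ln_n

    try:
        sol = optimize.least_squares(
            resid,
            x0=[mu0, np.log(K0), np.log(N00)],
            bounds=([0.0, np.log(dens.max() * 0.5), -np.inf],
                    [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        ok = bool(sol.success) and np.all(np.isfinite(sol.x))
        mu, k, n0 = sol.x[0], float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
        rss = float(2.0 * sol.cost)
    except Exception:
        ok, mu, k, n0, rss = False, float("nan"), float("nan"), float("nan"), float("nan")
    return LogisticFit(mu=float(mu), K=k, N0=n0, rss=rss, converged=ok)


def max_yield(curves: Iterable[GrowthCurve]) -> float:
    """Maximum cell yield: mean over replicates of each curve's peak density."""
    peaks = [float(c.density.max()) for c in curves]
    if not peaks:
        raise ValueError("max_yield requires at least one growth curve")
    return float(np.mean(peaks))


# ---------------------------------------------------------------- CSV I/O

GROWTH_COLUMNS = ("substrate", "replicate", "time_d", "cells_per_ml")


def read_growth_csv(path) -> list[GrowthCurve]:
    """Read growth curves from a CSV with columns substrate, replicate, time_d, cells_per_ml."""
    df = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV missing columns: {sorted(missing)}")
    curves = []
    for (sub, rep), grp in df.groupby(["substrate", "replicate"], sort=True):
        grp = grp.sort_values("time_d")
        curves.append(GrowthCurve(substrate=str(sub), replicate=str(rep),
                                  time=grp["time_d"].to_numpy(),
                                  density=grp["cells_per_ml"].to_numpy()))
    return curves


def write_growth_csv(curves: Sequence[GrowthCurve], path) -> None:
    rows = [
        {"substrate": c.substrate, "replicate": c.replicate,
         "time_d": t, "cells_per_ml": d}
        for c in curves for t, d in zip(c.time, c.density)
    ]
    pd.DataFrame(rows, columns=list(GROWTH_COLUMNS)).to_csv(path, index=False)


def fit_all(curves: Sequence[GrowthCurve], model: str = "window") -> pd.DataFrame:
    """Fit every curve and tabulate per-replicate rates plus per-substrate means."""
    rows = []
    for c in curves:
        if model == "logistic":
            fit = fit_logistic(c)
            rows.append({"substrate": c.substrate, "replicate": c.replicate,
                         "mu_per_day": fit.mu, "K_cells_per_ml": fit.K,
                         "N0_cells_per_ml": fit.N0, "converged": fit.converged})
        elif model == "window":
            est = exponential_growth_rate(c)
            rows.append({"substrate": c.substrate, "replicate": c.replicate,
                         "mu_per_day": est.mu, "r2": est.r2,
                         "n_points": est.n_points})
        else:
            raise ValueError(f"unknown model {model!r}")
    return pd.DataFrame(rows)
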