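"""Initial-velocity kinetics from probability series.

The reaction-rate statistic is the ordinary-least-squares slope of the
reactant-detection probability versus digestion time over the initial
velocity region (first 15 measured minutes by default), in percentage
points per minute.  The reported *reaction rate* is the negated slope
(positive for digestion).  Mean rates across replicates are related to the
enzyme amount by a second OLS fit, whose R² quantifies the linearity of
activity with enzyme concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .population_analysis import ProbabilitySeries

__all__ = [
    "KineticFit",
    "RateCurve",
    "fit_line",
    "fit_initial_velocity",
    "rate_vs_concentration",
    "classify_condition",
]


@dataclass(frozen=True)
class KineticFit:
    """OLS line through probability (%) vs time (min)."""

    slope: float  # percentage points / min
    intercept: float  # %
    stderr_slope: float
    r_squared: float
    window: tuple[float, float]  # (t_start, t_end), minutes, inclusive
    n_points: int
    degenerate: bool = False  # zero-variance response: r² reported as 0

    @property
    def rate(self) -> float:
        """Reaction rate, the negated slope (positive for digestion)."""
        return -self.slope


@dataclass(frozen=True)
class RateCurve:
    """Mean reaction rate per enzyme amount, with its linearity fit."""

    enzyme_units: np.ndarray
    rate: np.ndarray  # mean -slope per concentration, pp/min
    sem: np.ndarray  # standard error of the mean across replicates
    n_replicates: np.ndarray
    slope: float  # rate per unit
    intercept: float
    r_squared: float


def fit_line(t: np.ndarray, y: np.ndarray,
             window: tuple[float, float] | None = None) -> KineticFit:
    """Least-squares line with degenerate-response handling.

    A zero-variance response has mathematically undefined r²; it is reported
    as 0 with the ``degenerate`` flag set (slope and stderr are still exact).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 points for a kinetic fit, got {t.size}")
    if window is None:
        window = (float(t.min()), float(t.max()))
    if np.ptp(y) == 0.0:
        return KineticFit(
            slope=0.0, intercept=float(y[0]), stderr_slope=0.0, r_squared=0.0,
            window=window, n_points=int(t.size), degenerate=True,
        )
    res = sps.linregress(t, y)
    return KineticFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        r_squared=float(res.rvalue**2),
        window=window,
        n_points=int(t.size),
    )


def fit_initial_velocity(
    series: ProbabilitySeries, window: tuple[float, float] = (1, 15)
) -> KineticFit:
    """Fit the initial-velocity slope over ``window`` (minutes, inclusive).

    Unusable (NaN) minutes inside the window are dropped, not interpolated;
    at least 3 usable minutes are required.
    """
    lo, hi = window
    mask = (series.minutes >= lo) & (series.minutes <= hi) & series.usable()
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} usable minutes in window [{lo}, {hi}]; "
            "need at least 3"
        )
    return fit_line(series.minutes[mask], series.probability[mask], window=(lo, hi))


def rate_vs_concentration(
    fits: Sequence[tuple[float, Sequence[KineticFit]]]
) -> RateCurve:
    """Relate mean reaction rate to enzyme amount across concentrations.

    ``fits`` pairs each enzyme amount (units) with its replicate kinetic
    fits.  Per concentration the mean rate (−slope) and the standard error
    of the mean across replicates are computed; the rate-vs-units line is
    then fitted by OLS and its R² reported.
    """
    if len(fits) < 3:
        raise ValueError("need >= 3 enzyme concentrations for a rate curve")
    units, mean_rate, sem, n_rep = [], [], [], []
    for u, reps in fits:
        if len(reps) < 1:
            raise ValueError(f"no replicates for {u} units")
        rates = np.array([f.rate for f in reps], dtype=float)
        units.append(float(u))
        mean_rate.append(float(rates.mean()))
        n_rep.append(len(rates))
        sem.append(float(rates.std(ddof=1) / np.sqrt(len(rates)))
                   if len(rates) > 1 else 0.0)
    units = np.array(units)
    mean_rate = np.array(mean_rate)
    line = fit_line(units, mean_rate)
    return RateCurve(
        enzyme_units=units,
        rate=mean_rate,
        sem=np.array(sem),
        n_replicates=np.array(n_rep),
        slope=line.slope,
        intercept=line.intercept,
        r_squared=line.r_squared,
    )


def classify_condition(
    fit: KineticFit, inactive_above: float = -0.1, active_below: float = -1.0
) -> str:
    """Label a condition by its fitted slope.

    ``inactive`` for slopes above −0.1 pp/min (flat controls), ``active``
    below −1 pp/min (rapid digestion), ``weakly_active`` in between.
    """
    if fit.slope > inactive_above:
        return "inactive"
    if fit.slope < active_below:
        return "active"
    return "weakly_active"
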