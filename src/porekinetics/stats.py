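"""Replicate-level significance testing of detection probabilities.

Compares the per-replicate reactant-detection probability between two time
points (typically minute 1 vs minute 30) with a classical equal-variance
two-tailed unpaired t-test, gated on Levene's homoscedasticity test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "unpaired_t_two_tailed",
    "levene",
    "significance_code",
    "compare_groups",
]


def _as_group(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"group {name} needs n >= 2 replicates, got {x.size}")
    return x


def unpaired_t_two_tailed(a: Sequence[float], b: Sequence[float],
                          welch: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test (equal-variance Student form by default).

    The classical pooled-variance statistic with n_a + n_b − 2 degrees of
    freedom; ``welch=True`` switches to the unequal-variance form.  Zero
    pooled variance with equal means is the degenerate identity case
    (t = 0, p = 1).
    """
    a, b = _as_group(a, "a"), _as_group(b, "b")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return (-np.inf if a[0] < b[0] else np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def levene(a: Sequence[float], b: Sequence[float],
           center: str = "mean") -> tuple[float, float]:
    """Levene's test for equality of variances between two groups.

    Classical group-mean centering by default; ``center="median"`` gives the
    Brown–Forsythe variant.  P > 0.05 is taken as homoscedasticity.  Two
    location-shifted copies of the same spread pattern (or two constant
    groups) give W = 0, p = 1.
    """
    a, b = _as_group(a, "a"), _as_group(b, "b")
    za = np.abs(a - (a.mean() if center == "mean" else np.median(a)))
    zb = np.abs(b - (b.mean() if center == "mean" else np.median(b)))
    if np.ptp(np.concatenate([za, zb])) == 0:
        return 0.0, 1.0
    w, p = sps.levene(a, b, center=center)
    return float(w), float(p)


def significance_code(p: float) -> str:
    """Map a p-value to the assay's annotation scale.

    ``ns`` for p ≥ 0.05, ``*`` for p < 0.05, ``**`` for p < 0.005 and
    ``****`` for p < 0.0001 (the most extreme applicable tier; no ``***``
    tier is defined on this scale).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 5e-3:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """Minute-1 vs minute-30 style replicate comparison."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    levene_statistic: float
    levene_p: float
    code: str

    def to_row(self) -> dict:
        return {
            "group_a": self.label_a,
            "group_b": self.label_b,
            "mean_a": self.mean_a,
            "sem_a": self.sem_a,
            "mean_b": self.mean_b,
            "sem_b": self.sem_b,
            "t": self.t_statistic,
            "p": self.p_value,
            "levene_W": self.levene_statistic,
            "levene_p": self.levene_p,
            "significance": self.code,
        }


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "1 min",
    label_b: str = "30 min",
    welch: bool = False,
    levene_center: str = "mean",
) -> ComparisonResult:
    """Full replicate comparison: means ± SEM, t-test, Levene gate, code."""
    a_arr, b_arr = _as_group(a, "a"), _as_group(b, "b")
    t, p = unpaired_t_two_tailed(a_arr, b_arr, welch=welch)
    w, lp = levene(a_arr, b_arr, center=levene_center)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n_a=a_arr.size,
        n_b=b_arr.size,
        mean_a=float(a_arr.mean()),
        sem_a=float(a_arr.std(ddof=1) / np.sqrt(a_arr.size)),
        mean_b=float(b_arr.mean()),
        sem_b=float(b_arr.std(ddof=1) / np.sqrt(b_arr.size)),
        t_statistic=t,
        p_value=p,
        levene_statistic=w,
        levene_p=lp,
        code=significance_code(p),
    )
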