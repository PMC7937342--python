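"""Closed-form power and sample-size calculation for RNA-seq DE tests.

On the log scale a gene's count in one sample has approximate variance
1/depth + cv^2: Poisson counting noise at sequencing depth ``depth`` (average
reads per gene) plus biological variability cv^2, where cv is the biological
coefficient of variation — the square root of the negative-binomial common
dispersion. A two-sample normal test for a fold-change ``effect`` then has

    power = Phi( sqrt( n * ln(effect)^2 / (2 * (1/depth + cv^2)) ) - z_{1-alpha/2} )

and inverting for the replicate number per group gives

    n = 2 * (z_{1-alpha/2} + z_{power})^2 * (1/depth + cv^2) / ln(effect)^2 .

Replicate requirements are reported both as the real solution and rounded
to the nearest integer (half away from zero); a ceiling rule is deliberately
not used because the target power is itself approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class PowerParams:
    """One design point for the power calculation.

    n: replicates per group (real-valued, >= 1 for a meaningful design)
    depth: average sequencing coverage per gene, in reads (> 0)
    cv: biological coefficient of variation, sqrt of NB common dispersion
    effect: fold-change to detect (> 0, != 1)
    alpha: two-sided type-I error rate
    power: target power (used by sample-size solving only)
    """

    n: float = 4.0
    depth: float = 100.0
    cv: float = 0.35
    effect: float = 2.0
    alpha: float = 0.05
    power: float = 0.93

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.effect <= 0 or self.effect == 1.0:
            raise ValueError("effect must be positive and != 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0,1)")


def _variance_term(depth: float, cv: float) -> float:
    v = 1.0 / depth + cv * cv
    if v <= 0:
        raise ValueError("1/depth + cv^2 must be positive")
    return v


def power_at(n: float, depth: float, cv: float, effect: float, alpha: float = 0.05) -> float:
    """Power of the two-sided level-``alpha`` test at ``n`` replicates/group."""
    PowerParams(n=n, depth=depth, cv=cv, effect=effect, alpha=alpha)
    v = _variance_term(depth, cv)
    ncp = math.sqrt(n * math.log(effect) ** 2 / (2.0 * v))
    return float(norm.cdf(ncp - norm.ppf(1.0 - alpha / 2.0)))


def required_n(
    depth: float, cv: float, effect: float, alpha: float = 0.05, power: float = 0.93
) -> tuple[float, int]:
    """Replicates per group to reach ``power``; returns (real n, rounded n).

    Rounding is to the nearest integer, half away from zero; power_at of
    the real solution recovers ``power`` to 1e-9.
    """
    PowerParams(depth=depth, cv=cv, effect=effect, alpha=alpha, power=power)
    v = _variance_term(depth, cv)
    z = norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power)
    n_real = 2.0 * z * z * v / math.log(effect) ** 2
    n_int = int(math.floor(n_real + 0.5))  # half away from zero (n_real > 0)
    return float(n_real), n_int


def power_table(grid: Iterable[PowerParams]) -> pd.DataFrame:
    """Power at every design point of the grid, one row per combination."""
    rows = []
    for p in grid:
        rows.append({
            "n": p.n, "depth": p.depth, "cv": p.cv, "effect": p.effect,
            "alpha": p.alpha,
            "power": power_at(p.n, p.depth, p.cv, p.effect, p.alpha),
        })
    if not rows:
        raise ValueError("empty parameter grid")
    return pd.DataFrame(rows)


def all_female_probability(n_larvae: int, p_female: float = 0.5) -> float:
    """Probability that a pool of ``n_larvae`` individuals is all female at
    sex ratio ``p_female`` — the design-math check behind flagging a
    symbiont-free replicate that looks male-free (0.5^3 = 12.5% for 3)."""
    if n_larvae < 0:
        raise ValueError("n_larvae must be non-negative")
    if not 0 <= p_female <= 1:
        raise ValueError("p_female must be in [0,1]")
    return p_female ** n_larvae
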