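"""Analytic sample-size and power calculation for the SCCS design.

Uses the binomial approximation for a single exposure category: conditional
on a case having exactly one event, the event falls in exposed time with
probability :math:`\\pi_0 = r` under the null and
:math:`\\pi_1 = r\\rho / (r\\rho + 1 - r)` under the alternative, where
``r`` is the exposed fraction of observation time and ``rho`` the target
incidence rate ratio.  The required number of cases for a two-sided test is

.. math::

    n = \\left\\lceil \\frac{\\left(z_{1-\\alpha/2}\\sqrt{\\pi_0(1-\\pi_0)}
        + z_{\\mathrm{power}}\\sqrt{\\pi_1(1-\\pi_1)}\\right)^2}
        {(\\pi_1-\\pi_0)^2} \\right\\rceil .

Age effects are ignored, which is the standard planning simplification when
the exposed time fraction is taken as an overall average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateDesignError(ValueError):
    """The design cannot distinguish exposure effects (rho = 1 or r in {0, 1})."""


@dataclass(frozen=True)
class DesignSummary:
    """Planning inputs: exposed time fraction, target IRR, error rates."""

    r: float
    rho: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not 0 < self.r < 1:
            raise DegenerateDesignError(f"r must be in (0, 1), got {self.r}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")


def event_probabilities(r: float, rho: float) -> tuple[float, float]:
    """(pi0, pi1): chance a case's single event lies in exposed time."""
    pi0 = r
    pi1 = r * rho / (r * rho + 1 - r)
    return pi0, pi1


def required_cases(design: DesignSummary) -> int:
    """Minimum number of cases detecting ``rho`` at the design's alpha/power."""
    if design.rho == 1:
        raise DegenerateDesignError("rho = 1: a null effect cannot be detected")
    pi0, pi1 = event_probabilities(design.r, design.rho)
    z_a = stats.norm.ppf(1 - design.alpha / 2)
    z_b = stats.norm.ppf(design.power)
    num = (z_a * math.sqrt(pi0 * (1 - pi0)) + z_b * math.sqrt(pi1 * (1 - pi1))) ** 2
    return math.ceil(num / (pi1 - pi0) ** 2)


def power_given_cases(r: float, rho: float, n_cases: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test at a fixed number of cases (formula inverse)."""
    if rho == 1:
        raise DegenerateDesignError("rho = 1: a null effect cannot be detected")
    if not 0 < r < 1:
        raise DegenerateDesignError(f"r must be in (0, 1), got {r}")
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    pi0, pi1 = event_probabilities(r, rho)
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_power = (
        abs(pi1 - pi0) * math.sqrt(n_cases) - z_a * math.sqrt(pi0 * (1 - pi0))
    ) / math.sqrt(pi1 * (1 - pi1))
    return float(stats.norm.cdf(z_power))


def simulated_power(
    r: float,
    rho: float,
    n_cases: int,
    alpha: float = 0.05,
    n_replicates: int = 50_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided Wald test on the exposure log-IRR.

    Each replicate places ``n_cases`` single events into exposed time with
    probability ``pi1`` (binomial draw), estimates the IRR as
    ``k (1 - r) / ((n - k) r)`` and rejects when the Wald statistic
    ``|log irr| / sqrt(1/k + 1/(n-k))`` exceeds the normal critical value
    (degenerate splits with k = 0 or k = n always reject).

    Note that the analytic formula in :func:`power_given_cases` is a plain
    normal approximation; at small case counts the exact (binomial) power it
    approximates can differ by a few percentage points.
    """
    pi0, pi1 = event_probabilities(r, rho)
    rng = np.random.default_rng(seed)
    z_a = stats.norm.ppf(1 - alpha / 2)
    k = rng.binomial(n_cases, pi1, n_replicates)
    degenerate = (k == 0) | (k == n_cases)
    ks = np.clip(k, 1, n_cases - 1)
    log_irr = np.log(ks / (n_cases - ks) * ((1 - r) / r))
    se = np.sqrt(1.0 / ks + 1.0 / (n_cases - ks))
    reject = degenerate | (np.abs(log_irr) / se > z_a)
    return float(reject.mean())
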