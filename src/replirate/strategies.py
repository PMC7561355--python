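"""Analytic p-hacking strategies: effective Type-1 error and power.

Three strategies admit closed analytic treatment through multivariate
normal orthant/box probabilities of the k z-statistics a p-hacker gets to
look at:

* selective reporting — run up to k independent studies, publish the first
  significant one.  The statistics are independent, so
  P(reject) = 1 - (1 - p_single)**k.
* multiple dependent measures — test k equicorrelated measures (pairwise
  correlation rho) in one study and report any significant one.
  P(reject) = 1 - P(Z_1 <= c, ..., Z_k <= c) for an equicorrelated MVN.
* data peeking — test the accumulating sample at sizes n_1 < ... < n_k,
  stopping at the first significant look.  Because early observations are
  reused, Corr(Z_i, Z_j) = sqrt(n_i / n_j) for n_i <= n_j.

Each strategy's *effective* Type-1 error is its rejection probability at
d = 0 and its *effective* power the rejection probability at the true d;
the pair feeds the replication-rate arithmetic in :mod:`replirate.core`.

Equicorrelated orthant probabilities are computed by the one-factor
reduction (a single quadrature over the shared factor); the general
peeking correlation structure goes through scipy's Genz MVN routine with a
frozen internal QMC seed so results are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .core import (
    StudyDesign,
    Tails,
    TestForm,
    critical_value,
    noncentrality,
    ztest_rejection_prob,
)

__all__ = [
    "PeekSchedule",
    "MeasureBattery",
    "FIGURE_SCHEDULE",
    "TEN_STEP_SCHEDULE",
    "selective_reporting_rejection",
    "multiple_measures_rejection",
    "data_peeking_rejection",
    "peek_correlation_matrix",
    "Strategy",
    "SelectiveReporting",
    "MultipleMeasures",
    "DataPeeking",
    "effective_rates_for_strategy",
]

# Internal QMC seed for the Genz MVN integrator; fixed so that identical
# inputs always produce identical probabilities (byte-stable grid output).
_MVN_SEED = 186283


@dataclass(frozen=True)
class PeekSchedule:
    """Strictly increasing per-group sample sizes at which a peeker tests."""

    sample_sizes: tuple[int, ...]

    def __init__(self, sample_sizes: Sequence[int]) -> None:
        sizes = tuple(int(n) for n in sample_sizes)
        if len(sizes) < 1:
            raise ValueError("schedule must contain at least one sample size")
        if sizes[0] < 2:
            raise ValueError("sample sizes must be >= 2")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"schedule must be strictly increasing, got {sizes}")
        object.__setattr__(self, "sample_sizes", sizes)

    def __len__(self) -> int:
        return len(self.sample_sizes)

    def truncated(self, k: int) -> "PeekSchedule":
        """First k looks of the schedule."""
        if not 1 <= k <= len(self.sample_sizes):
            raise ValueError(f"k must be in 1..{len(self.sample_sizes)}")
        return PeekSchedule(self.sample_sizes[:k])


#: Looks every 5 observations from 10 to 45 per group (the default grid).
FIGURE_SCHEDULE = PeekSchedule((10, 15, 20, 25, 30, 35, 40, 45))
#: First look at n=10 then four increments of 10 — the classic benchmark
#: schedule whose two-sided Type-1 error is about 14%.
TEN_STEP_SCHEDULE = PeekSchedule((10, 20, 30, 40, 50))


@dataclass(frozen=True)
class MeasureBattery:
    """k dependent measures with common pairwise intercorrelation rho."""

    k: int
    rho: float = 0.2

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


def selective_reporting_rejection(design: StudyDesign, k: int) -> float:
    """P(at least one of k independent studies rejects H0)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p1 = ztest_rejection_prob(design)
    return 1.0 - (1.0 - p1) ** k


def _equicorrelated_nonexceed(
    c: float, k: int, rho: float, delta: float, tails: Tails
) -> float:
    """P(all k statistics stay below c / inside [-c, c]) for the
    equicorrelated MVN with common mean ``delta`` and correlation ``rho``.

    Uses the one-factor representation Z_i = sqrt(rho)*U + sqrt(1-rho)*e_i
    + delta, conditioning on the shared factor U and integrating it out.
    """
    if rho == 0.0:
        if tails is Tails.TWO_SIDED:
            p1 = stats.norm.cdf(c - delta) - stats.norm.cdf(-c - delta)
        else:
            p1 = stats.norm.cdf(c - delta)
        return float(p1**k)
    s = math.sqrt(1.0 - rho)
    r = math.sqrt(rho)

    if tails is Tails.TWO_SIDED:

        def integrand(u: float) -> float:
            upper = stats.norm.cdf((c - delta - r * u) / s)
            lower = stats.norm.cdf((-c - delta - r * u) / s)
            return stats.norm.pdf(u) * (upper - lower) ** k

    else:

        def integrand(u: float) -> float:
            return stats.norm.pdf(u) * stats.norm.cdf((c - delta - r * u) / s) ** k

    value, abserr = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-10, limit=200)
    if abserr > 1e-6:
        raise ArithmeticError(
            f"orthant quadrature did not converge: abserr={abserr:g} "
            f"(c={c}, k={k}, rho={rho}, delta={delta})"
        )
    return min(max(value, 0.0), 1.0)


def multiple_measures_rejection(design: StudyDesign, battery: MeasureBattery) -> float:
    """P(at least one of k correlated dependent measures is significant)."""
    c = critical_value(design.alpha_nominal, design.tails)
    delta = noncentrality(design.test_form, design.effect_size, design.n_per_group)
    p_none = _equicorrelated_nonexceed(c, battery.k, battery.rho, delta, design.tails)
    return 1.0 - p_none


def peek_correlation_matrix(schedule: PeekSchedule) -> np.ndarray:
    """Correlation matrix of sequential z-statistics sharing early data."""
    n = np.asarray(schedule.sample_sizes, dtype=float)
    return np.sqrt(np.minimum.outer(n, n) / np.maximum.outer(n, n))


def data_peeking_rejection(design: StudyDesign, schedule: PeekSchedule) -> float:
    """P(some look at the accumulating data is significant).

    The design's ``n_per_group`` is ignored; the schedule supplies the
    sample sizes.  A single-look schedule reduces to the fixed-n test.
    """
    sizes = schedule.sample_sizes
    c = critical_value(design.alpha_nominal, design.tails)
    deltas = np.array(
        [noncentrality(design.test_form, design.effect_size, n) for n in sizes]
    )
    if len(sizes) == 1:
        return ztest_rejection_prob(design.with_n(sizes[0]))
    corr = peek_correlation_matrix(schedule)
    mvn = stats.multivariate_normal(mean=deltas, cov=corr, seed=_MVN_SEED)
    upper = np.full(len(sizes), c)
    if design.tails is Tails.TWO_SIDED:
        p_none = mvn.cdf(upper, lower_limit=-upper)
    else:
        p_none = mvn.cdf(upper)
    return 1.0 - float(np.clip(p_none, 0.0, 1.0))


class Strategy:
    """Base class: a p-hacking behaviour around a fixed study design.

    Subclasses implement :meth:`rejection_prob`; ``effective_rates``
    evaluates it at d=0 (Type-1 error) and at the true d (power), and
    ``good_practice_rates`` gives the non-hacking reference the strategy
    is compared against.
    """

    name: str
    design: StudyDesign

    def rejection_prob(self, d: float | None = None) -> float:
        raise NotImplementedError

    def effective_rates(self, d: float) -> tuple[float, float]:
        """(effective Type-1 error, effective power) at effect size d."""
        if d < 0:
            raise ValueError("effect size must be >= 0")
        return self.rejection_prob(0.0), self.rejection_prob(d)

    def good_practice_rates(self, d: float) -> tuple[float, float]:
        """Reference (alpha, power) for a researcher running one clean test."""
        if d < 0:
            raise ValueError("effect size must be >= 0")
        design = self._good_practice_design()
        return design.alpha_nominal, ztest_rejection_prob(design.with_effect(d))

    def _good_practice_design(self) -> StudyDesign:
        return self.design


@dataclass(frozen=True)
class SelectiveReporting(Strategy):
    """Publish the first significant of up to k independent studies."""

    design: StudyDesign
    k: int = 1
    name = "selective-reporting"

    def rejection_prob(self, d: float | None = None) -> float:
        design = self.design if d is None else self.design.with_effect(d)
        return selective_reporting_rejection(design, self.k)


@dataclass(frozen=True)
class MultipleMeasures(Strategy):
    """Report any significant one of k correlated dependent measures."""

    design: StudyDesign
    battery: MeasureBattery = MeasureBattery(k=1)
    name = "multiple-measures"

    def rejection_prob(self, d: float | None = None) -> float:
        design = self.design if d is None else self.design.with_effect(d)
        return multiple_measures_rejection(design, self.battery)


@dataclass(frozen=True)
class DataPeeking(Strategy):
    """Test the growing sample at each scheduled size, stop when significant.

    The good-practice reference is a single preplanned test at the
    schedule's final (maximal) sample size — a deliberately conservative
    comparison, since the honest researcher gets the peeker's largest n.
    """

    design: StudyDesign
    schedule: PeekSchedule = FIGURE_SCHEDULE
    name = "data-peeking"

    def rejection_prob(self, d: float | None = None) -> float:
        design = self.design if d is None else self.design.with_effect(d)
        return data_peeking_rejection(design, self.schedule)

    def _good_practice_design(self) -> StudyDesign:
        return self.design.with_n(self.schedule.sample_sizes[-1])


def effective_rates_for_strategy(strategy: Strategy, d: float) -> tuple[float, float]:
    """(alpha_eff, power_eff) of a strategy at effect size d."""
    return strategy.effective_rates(d)
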