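"""Closed-form arithmetic of the replication scenario.

The scenario: a field tests hypotheses of which a fraction ``pi`` (the base
rate) are true effects.  An original study rejects H0 with probability
``power1_eff`` when the effect is real and ``alpha1_eff`` when it is not;
these *effective* rates may be inflated above their nominal values by
questionable research practices.  Significant originals are then subjected
to an unbiased direct replication run at nominal level ``alpha2`` with
power ``power2``.

Two quantities summarise the scenario:

* the replication rate ``RR`` — the probability that the replication of an
  initially significant result is itself significant,

      RR = [pi * power1 * power2 + (1-pi) * alpha1 * alpha2]
           / [pi * power1 + (1-pi) * alpha1]

* the false positive rate ``FPR`` (false discovery rate) — the share of
  false positives among all significant originals,

      FPR = (1-pi) * alpha1 / [(1-pi) * alpha1 + pi * power1]

All tests are modelled as z-tests with known unit variance; under H1 the
z-statistic has noncentral mean ``d*sqrt(n)`` (one-sample) or
``d*sqrt(n/2)`` (two-sample) for a standardized effect size d.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

from scipy import stats

__all__ = [
    "TestForm",
    "Tails",
    "UndefinedRateError",
    "ScenarioParams",
    "StudyDesign",
    "critical_value",
    "noncentrality",
    "ztest_rejection_prob",
    "replication_rate",
    "false_positive_rate",
    "all_significant_prob",
    "any_of_m_effects_prob",
]


class TestForm(str, enum.Enum):
    """Form of the z-test: a single group against a constant, or two groups."""

    ONE_SAMPLE = "one_sample"
    TWO_SAMPLE = "two_sample"


class Tails(str, enum.Enum):
    ONE_SIDED = "one_sided"
    TWO_SIDED = "two_sided"


class UndefinedRateError(ValueError):
    """Raised when a conditional rate has probability-zero conditioning event.

    Happens for 0/0 parameter corners, e.g. pi=0 with alpha1_eff=0 (no
    significant originals can exist, so "the replication rate" is undefined).
    A loud error is preferred over a silent NaN that would corrupt grid tables.
    """


def _check_prob(name: str, value: float, *, open_interval: bool = False) -> None:
    if open_interval:
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {value!r}")
    elif not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of one replication scenario.

    ``alpha1_eff`` and ``power1_eff`` are the *effective* Type-1 error and
    power of the original study; p-hacking strategies produce values above
    the nominal ones, which is legal input here.
    """

    base_rate: float
    alpha1_eff: float
    power1_eff: float
    alpha2: float = 0.05
    power2: float = 0.90

    def __post_init__(self) -> None:
        _check_prob("base_rate", self.base_rate)
        _check_prob("alpha1_eff", self.alpha1_eff)
        _check_prob("power1_eff", self.power1_eff)
        _check_prob("alpha2", self.alpha2, open_interval=True)
        _check_prob("power2", self.power2, open_interval=True)


@dataclass(frozen=True)
class StudyDesign:
    """Testing setup of a single original study.

    ``effect_size`` is Cohen's d; d = 0 encodes a true null.
    """

    test_form: TestForm = TestForm.TWO_SAMPLE
    n_per_group: int = 20
    effect_size: float = 0.0
    alpha_nominal: float = 0.05
    tails: Tails = Tails.ONE_SIDED

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_form", TestForm(self.test_form))
        object.__setattr__(self, "tails", Tails(self.tails))
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        _check_prob("alpha_nominal", self.alpha_nominal, open_interval=True)

    def with_effect(self, d: float) -> "StudyDesign":
        return replace(self, effect_size=d)

    def with_n(self, n: int) -> "StudyDesign":
        return replace(self, n_per_group=n)


def critical_value(alpha_nominal: float, tails: Tails | str) -> float:
    """Critical z cutoff: P(Z > c) = alpha (one-sided) or P(|Z| > c) = alpha."""
    _check_prob("alpha_nominal", alpha_nominal, open_interval=True)
    tails = Tails(tails)
    if tails is Tails.TWO_SIDED:
        return float(stats.norm.isf(alpha_nominal / 2.0))
    return float(stats.norm.isf(alpha_nominal))


def noncentrality(test_form: TestForm | str, d: float, n_per_group: int) -> float:
    """Mean shift of the z-statistic under an effect of size d."""
    if TestForm(test_form) is TestForm.ONE_SAMPLE:
        return d * math.sqrt(n_per_group)
    return d * math.sqrt(n_per_group / 2.0)


def _shifted_rejection_prob(delta: float, c: float, tails: Tails) -> float:
    # Z ~ N(delta, 1); two-sided includes the (tiny) lower-tail term exactly.
    if tails is Tails.TWO_SIDED:
        return float(stats.norm.sf(c - delta) + stats.norm.cdf(-c - delta))
    return float(stats.norm.sf(c - delta))


def ztest_rejection_prob(design: StudyDesign) -> float:
    """P(reject H0) for a single z-test under the design's effect size.

    Equals ``alpha_nominal`` exactly when ``effect_size`` is 0.
    """
    c = critical_value(design.alpha_nominal, design.tails)
    delta = noncentrality(design.test_form, design.effect_size, design.n_per_group)
    return _shifted_rejection_prob(delta, c, design.tails)


def replication_rate(s: ScenarioParams) -> float:
    """Probability that the replication of a significant original rejects.

    The endpoints pi = 0 and pi = 1 are returned through their algebraic
    limits (alpha2 and power2) so they are exact rather than rounded.
    """
    pi = s.base_rate
    if pi == 0.0:
        if s.alpha1_eff == 0.0:
            raise UndefinedRateError("pi=0 with alpha1_eff=0: no significant originals")
        return s.alpha2
    if pi == 1.0:
        if s.power1_eff == 0.0:
            raise UndefinedRateError("pi=1 with power1_eff=0: no significant originals")
        return s.power2
    denom = pi * s.power1_eff + (1.0 - pi) * s.alpha1_eff
    if denom <= 0.0:
        raise UndefinedRateError("no significant originals under these parameters")
    num = pi * s.power1_eff * s.power2 + (1.0 - pi) * s.alpha1_eff * s.alpha2
    return num / denom


def false_positive_rate(base_rate: float, alpha1_eff: float, power1_eff: float) -> float:
    """Share of false positives among all significant original results."""
    _check_prob("base_rate", base_rate)
    _check_prob("alpha1_eff", alpha1_eff)
    _check_prob("power1_eff", power1_eff)
    pi = base_rate
    if pi == 0.0:
        if alpha1_eff == 0.0:
            raise UndefinedRateError("pi=0 with alpha1_eff=0: no significant originals")
        return 1.0
    if pi == 1.0:
        if power1_eff == 0.0:
            raise UndefinedRateError("pi=1 with power1_eff=0: no significant originals")
        return 0.0
    denom = (1.0 - pi) * alpha1_eff + pi * power1_eff
    if denom <= 0.0:
        raise UndefinedRateError("no significant originals under these parameters")
    return (1.0 - pi) * alpha1_eff / denom


def all_significant_prob(single_power: float, k: int) -> float:
    """P(k independent studies all reject) = power ** k.

    An observed run of k significant studies at modest single-study power is
    improbable; e.g. 0.36 ** 5 = 0.006 — an "excess of positive results".
    """
    _check_prob("single_power", single_power)
    if k < 1:
        raise ValueError("k must be >= 1")
    return single_power**k


def any_of_m_effects_prob(alpha_nominal: float, m: int) -> float:
    """P(at least one of m independent null tests rejects) = 1 - (1-alpha)**m.

    E.g. a three-factor ANOVA offers 7 effect tests; at alpha=0.05 some
    effect is "found" about 30% of the time under a global null.
    """
    _check_prob("alpha_nominal", alpha_nominal, open_interval=True)
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha_nominal) ** m
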