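"""Agent-level Monte-Carlo oracle.

Everything the analytic modules compute in closed form is re-derived here
by brute force: simulated researchers draw raw data, apply their
p-hacking rule, and (optionally) hand significant results to a simulated
replication team.  The oracle deliberately shares no code path with the
analytic formulas — correlated measures are built from an explicit common
factor, peeking statistics from literally reused observations — so
agreement between the two is a genuine cross-check.

Replication studies are drawn as Bernoulli events at (alpha2, power2),
matching the scenario arithmetic's abstraction; ``replication_design``
switches to an explicit raw-data z-test replication for sensitivity
checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _replace

import numpy as np

from .core import StudyDesign, Tails, TestForm, critical_value
from .outliers import OutlierRemoval, run_outlier_strategy_once
from .strategies import DataPeeking, MultipleMeasures, SelectiveReporting

__all__ = [
    "OracleRun",
    "MCEstimate",
    "PipelineEstimate",
    "simulate_original_study",
    "mc_rejection_prob",
    "simulate_replication_pipeline",
]


@dataclass(frozen=True)
class MCEstimate:
    estimate: float
    se: float
    n_reps: int


@dataclass(frozen=True)
class PipelineEstimate:
    rr_hat: float
    rr_se: float
    fpr_hat: float
    fpr_se: float
    n_significant: int
    n_reps: int


@dataclass(frozen=True)
class OracleRun:
    """One oracle experiment: a strategy inside a replication scenario."""

    strategy: object
    base_rate: float
    effect_size: float
    alpha2: float = 0.05
    power2: float = 0.90
    n_reps: int = 100_000
    seed: int = 0
    replication_design: StudyDesign | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be in [0, 1]")
        if self.n_reps < 1000:
            raise ValueError("n_reps must be >= 1000 for a published comparison")


def _exceeds(z: np.ndarray, c: float, tails: Tails) -> np.ndarray:
    if tails is Tails.TWO_SIDED:
        return np.abs(z) > c
    return z > c


def _sim_selective(
    strat: SelectiveReporting, d: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    design = strat.design
    delta = _delta(design, d, design.n_per_group)
    c = critical_value(design.alpha_nominal, design.tails)
    z = rng.standard_normal((n_reps, strat.k)) + delta
    return _exceeds(z, c, design.tails).any(axis=1)


def _sim_measures(
    strat: MultipleMeasures, d: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    design = strat.design
    k, rho = strat.battery.k, strat.battery.rho
    delta = _delta(design, d, design.n_per_group)
    c = critical_value(design.alpha_nominal, design.tails)
    # One shared factor realizes the exact equicorrelation structure.
    u = rng.standard_normal((n_reps, 1))
    eps = rng.standard_normal((n_reps, k))
    z = math.sqrt(rho) * u + math.sqrt(1.0 - rho) * eps + delta
    return _exceeds(z, c, design.tails).any(axis=1)


def _sim_peeking(
    strat: DataPeeking, d: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Peeking from literally accumulating observations, in batches."""
    design = strat.design
    sizes = strat.schedule.sample_sizes
    n_max = sizes[-1]
    c = critical_value(design.alpha_nominal, design.tails)
    any_sig = np.zeros(n_reps, dtype=bool)
    batch = max(1, min(n_reps, 50_000))
    done = 0
    while done < n_reps:
        m = min(batch, n_reps - done)
        if design.test_form is TestForm.TWO_SAMPLE:
            exp = rng.standard_normal((m, n_max)) + d
            ctrl = rng.standard_normal((m, n_max))
            diff_cum = np.cumsum(exp - ctrl, axis=1)
            sig = np.zeros(m, dtype=bool)
            for n in sizes:
                z = diff_cum[:, n - 1] / math.sqrt(2.0 * n)
                sig |= _exceeds(z, c, design.tails)
        else:
            x = rng.standard_normal((m, n_max)) + d
            x_cum = np.cumsum(x, axis=1)
            sig = np.zeros(m, dtype=bool)
            for n in sizes:
                z = x_cum[:, n - 1] / math.sqrt(n)
                sig |= _exceeds(z, c, design.tails)
        any_sig[done : done + m] = sig
        done += m
    return any_sig


def _sim_outliers(
    strat: OutlierRemoval, d: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    config = _replace(strat.config, effect_size=d)
    out = np.empty(n_reps, dtype=bool)
    for i in range(n_reps):
        out[i] = run_outlier_strategy_once(config, rng)
    return out


def _delta(design: StudyDesign, d: float, n: int) -> float:
    if design.test_form is TestForm.ONE_SAMPLE:
        return d * math.sqrt(n)
    return d * math.sqrt(n / 2.0)


def _simulate_rejections(
    strategy: object, d: float, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    if d < 0:
        raise ValueError("effect size must be >= 0")
    if isinstance(strategy, SelectiveReporting):
        return _sim_selective(strategy, d, n_reps, rng)
    if isinstance(strategy, MultipleMeasures):
        return _sim_measures(strategy, d, n_reps, rng)
    if isinstance(strategy, DataPeeking):
        return _sim_peeking(strategy, d, n_reps, rng)
    if isinstance(strategy, OutlierRemoval):
        return _sim_outliers(strategy, d, n_reps, rng)
    raise TypeError(f"no oracle simulator for {type(strategy).__name__}")


def simulate_original_study(
    strategy: object, truth: str, rng: np.random.Generator, effect_size: float = 0.5
) -> bool:
    """Run one simulated original study; returns whether it came out significant.

    ``truth`` is "null" or "effect"; under "effect" the strategy's study
    measures a true standardized effect of ``effect_size``.
    """
    if truth not in ("null", "effect"):
        raise ValueError("truth must be 'null' or 'effect'")
    d = effect_size if truth == "effect" else 0.0
    return bool(_simulate_rejections(strategy, d, 1, rng)[0])


def mc_rejection_prob(
    strategy: object, d: float, n_reps: int, seed: int
) -> MCEstimate:
    """Monte-Carlo rejection probability of a strategy at effect size d."""
    rng = np.random.default_rng(seed)
    sig = _simulate_rejections(strategy, d, n_reps, rng)
    p = float(sig.mean())
    return MCEstimate(p, math.sqrt(p * (1.0 - p) / n_reps), n_reps)


def simulate_replication_pipeline(run: OracleRun) -> PipelineEstimate:
    """Simulate the full publish-then-replicate pipeline.

    Per replicate: the hypothesis is true with probability ``base_rate``;
    the original study runs under the strategy; if it is significant, the
    replication succeeds with probability ``power2`` (true effect) or
    ``alpha2`` (null) — or, when ``replication_design`` is given, by an
    explicit z-test on fresh data.  Returns the replication success rate
    among significant originals (RR) and the false-positive share among
    them (FPR), each with a binomial standard error.
    """
    rng = np.random.default_rng(run.seed)
    truth = rng.random(run.n_reps) < run.base_rate
    # Strategy outcomes are drawn under both truth values and selected
    # per-replicate; the unused draw is independent noise.
    sig_null = _simulate_rejections(run.strategy, 0.0, run.n_reps, rng)
    sig_eff = _simulate_rejections(run.strategy, run.effect_size, run.n_reps, rng)
    sig = np.where(truth, sig_eff, sig_null)
    n_sig = int(sig.sum())
    if n_sig == 0:
        raise ArithmeticError("no significant originals simulated; RR undefined")
    if run.replication_design is None:
        p_succ = np.where(truth, run.power2, run.alpha2)
        success = rng.random(run.n_reps) < p_succ
    else:
        rd = run.replication_design
        c = critical_value(rd.alpha_nominal, rd.tails)
        delta = _delta(rd, run.effect_size, rd.n_per_group)
        z = rng.standard_normal(run.n_reps) + np.where(truth, delta, 0.0)
        success = _exceeds(z, c, rd.tails)
    rr = float(success[sig].mean())
    fpr = float((~truth[sig]).mean())
    rr_se = math.sqrt(rr * (1.0 - rr) / n_sig)
    fpr_se = math.sqrt(fpr * (1.0 - fpr) / n_sig)
    return PipelineEstimate(rr, rr_se, fpr, fpr_se, n_sig, run.n_reps)
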