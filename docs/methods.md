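# Methods

## The replication scenario

The model treats a research field as a population of hypotheses, a
fraction π of which are true effects. An original study rejects H0 with
probability 1−β₁ when the effect is real and α₁ when it is not. Only
significant originals enter replication; an unbiased direct replication
rejects with probability 1−β₂ (true effect) or α₂ (null). Conditioning on
a significant original, the law of total probability gives

RR = [π(1−β₁)(1−β₂) + (1−π)α₁α₂] / [π(1−β₁) + (1−π)α₁],
FPR = (1−π)α₁ / [(1−π)α₁ + π(1−β₁)].

RR is a convex combination of α₂ and 1−β₂ and therefore always lies
between them: no property of the original study — including arbitrarily
extreme p-hacking — can push the replication rate outside that band. In
the worst case (α₁, 1−β₁ → 1) RR degenerates to the straight line
π(1−β₂) + (1−π)α₂.

Assumptions worth making explicit:

* Replication success is significance of the replication study, full
  stop; direction consistency is not modelled (the scenario formula has
  no directionality term).
* The replication is abstracted to its two probabilities (α₂, 1−β₂); the
  oracle also provides a raw-data replication mode (an explicit z-test at
  a chosen n) used as a sensitivity check in the tests.
* All analytic tests are z-tests with known unit variance. Under an
  effect of standardized size d, the z-statistic has mean d·√n
  (one-sample) or d·√(n/2) (two-sample, n per group). t-tests appear only
  in the outlier-removal simulation, which works on raw data.
* Two-sided tests reject on |Z| > c and the rejection probability under
  H1 includes the (negligible) wrong-tail term exactly.

Degenerate corners (π = 0 with α₁ = 0, π = 1 with 1−β₁ = 0) raise
`UndefinedRateError` rather than returning NaN, so a grid evaluation
cannot silently propagate undefined cells; grid rows record the
annotation instead. The exact endpoints π ∈ {0, 1} are returned through
their algebraic limits (α₂ and 1−β₂) so they are free of float rounding.

## P-hacking strategies

Each strategy is a rule for extracting one significance decision from k
opportunities. Its *effective* Type-1 error is the rejection probability
at d = 0, its *effective* power the rejection probability at the true d;
both feed the scenario formulas. Effect sizes are assumed homogeneous
across a strategy's studies, measures and looks.

**Selective reporting.** k independent studies (fresh samples), publish
if any rejects: P = 1 − (1−p₁)ᵏ with p₁ the single-test rejection
probability. At k = 8, one-sided α = 5%: 1 − 0.95⁸ = 0.337; at α = 0.5%:
0.039.

**Multiple dependent measures.** One study, k measures whose z-statistics
are equicorrelated with pairwise correlation ρ (default 0.2; ρ is
restricted to [0, 1)). P = 1 − P(Z₁≤c, …, Z_k≤c). The orthant/box
probability is computed by the one-factor reduction

P(all Zᵢ ≤ c) = ∫ φ(u) Φ((c − δ − √ρ·u)/√(1−ρ))ᵏ du,

evaluated with adaptive quadrature (`scipy.integrate.quad`, absolute
tolerance 1e−10, hard failure if the reported error exceeds 1e−6);
two-sided designs use the analogous box integrand. ρ = 0 reduces to the
selective-reporting product; ρ → 1 collapses to a single test. At k = 10,
ρ = 0.2, one-sided 5%, the null inflation is 33.8% ("5% → 34%").

**Data peeking.** Looks at per-group sizes n₁ < … < n_k; because early
observations are reused, Corr(Zᵢ, Zⱼ) = √(nᵢ/nⱼ). P = 1 − P(all looks
non-significant) via the multivariate normal CDF (Genz algorithm,
`scipy.stats.multivariate_normal` frozen with a fixed internal QMC seed,
so identical inputs give bit-identical output). Two presets ship: looks
every 5 from 10 to 45 (`FIGURE_SCHEDULE`, the default k-sweep) and
10,20,…,50 (`TEN_STEP_SCHEDULE`), whose two-sided 5% inflation is 14.17%
analytically — the classic simulation-based figure for this schedule is
14.3%, obtained with t-tests rather than z-tests. One-sided tests are the
package default everywhere; the 14%-benchmark schedule is two-sided
because that is how the benchmark is defined.

The good-practice reference for selective reporting and multiple measures
is the single test (k = 1) at the same design; for data peeking it is one
preplanned test at the schedule's *final* sample size — a deliberately
conservative baseline that concedes the p-hacker's maximal n to the
honest researcher. References do not depend on k, making them fixed
baselines across a k-sweep.

## Selective outlier removal (simulation)

No closed form exists, so this strategy is estimated by Monte Carlo.
Each replication draws one experiment: n = 20 per group (default),
scores standard normal around the group mean (the experimental group is
shifted by d), and each observation independently receives additive
N(0, 10²) noise with probability 0.05 — the contaminated-normal recipe,
mixture variance 1 + 0.05·100 = 6. The researcher then runs up to five
analyses, stopping at the first p < α (one-tailed):

1–3. pooled-variance t-tests keeping scores within 3, 2.5, 2 sample SDs
of their group mean (single pass, per group, ddof = 1);
4. t-test keeping scores inside the Tukey fences [Q1 − 1.5·IQR,
Q3 + 1.5·IQR], quartiles by linear interpolation (the convention is a
config knob, since fence membership at n = 20 can flip under Tukey's
original hinge rule);
5. a rank test on the *unfiltered* data — Mann-Whitney U (normal
approximation, tie- and continuity-corrected, verified against scipy to
1e−12) for two samples, Wilcoxon signed-rank for one sample.

Filtering is per group because under H1 the groups have different
locations and pooled filtering would bias the effect estimate. A filter
that removes every observation (or leaves fewer than two, or zero
variance) counts as a non-significant analysis and the sequence
continues; such events are counted and reported. `mode="full_data_first"`
models the alternative behaviour in which analysis #1 is an unfiltered
t-test and the remaining k−1 analyses are the leading filter steps, so a
one-analysis sequence in that mode is exactly a plain t-test. The default
is `filter_first` (researchers screen outliers before ever testing).

Each replication uses `numpy` generator seeded by (seed, replication
index), so truncating the analysis sequence re-analyses *identical* data
sets — rejection frequency is then provably nondecreasing in sequence
length, and estimates are bit-reproducible. Default 10,000 replications
give a binomial standard error below 0.005 on any probability.

## The Monte-Carlo oracle

`replirate.oracle` re-derives every analytic quantity by simulating the
agents directly, sharing no code with the closed forms: correlated
measures are built from an explicit common factor
Zᵢ = √ρ·U + √(1−ρ)·εᵢ + δ (which realizes the equicorrelation matrix by
construction), and peeking statistics are computed from literally
accumulated observations (realizing √(nᵢ/nⱼ) by construction). The
pipeline simulator draws the hypothesis truth at rate π, runs the
original study under the strategy, and replicates significant ones as
Bernoulli(1−β₂ or α₂) draws. The master consistency test requires every
analytic value across a parameter sweep to fall within 3 binomial
standard errors of its oracle estimate at 10⁵ replications.

## Grids and reporting

`evaluate_grid` materializes RR, FPR and shrinkage
(= RR_good − RR_hacked) over π × k × d × α₁ as a long-format
`pandas.DataFrame`. Defaults mirror the canonical scenario: n = 20 per
group, d ∈ {0.2, 0.5, 0.8}, α₁ ∈ {0.5%, 5%}, α₂ = 0.05, 1−β₂ = 0.90,
π from 0 to 1 in steps of 0.05 (resolution chosen for smoothness).
Shrinkage is *not* sign-constrained: power inflation occasionally makes
the hacked pipeline replicate slightly better, and the outlier-removal
scenario exhibits this. Tables are written as RFC-4180 CSV (or JSON) with
`#` metadata headers carrying the package version and the resolved
parameter set, deterministic row order, and 12-significant-digit floats
that round-trip losslessly; re-running an identical configuration
produces a byte-identical file. Figures are deliberately reproduced as
tables, not images — numbers are testable.

The headline comparison in the acceptance suite summarises the model per
strategy: the largest shrinkage anywhere on the default grid is compared
against the largest RR range spanned by the base rate alone (π: 0.05 →
0.95) under good practice. Note the comparison is per strategy, not per
(α, d) stratum — in the rare-true-effects/high-power corner (α = 0.5%,
d = 0.8) shrinkage genuinely exceeds the within-stratum base-rate spread,
which is exactly the corner where p-hacking matters most.

## Problem sizes and numerical choices

Analytic benchmarks are exact or quadrature-accurate to ≤1e−6. Simulation
sizes used by the tests: 10⁵ replications for oracle-vs-analytic
agreement (3 SE criterion), 10⁶ for the tightest orthant cross-checks,
10⁴ for outlier-removal estimates (the scale at which those results are
quoted). The MVN CDF's internal QMC seed is fixed; all other randomness
flows from explicit user seeds.

## What the model does not cover

* Empirical estimation of π from observed replication data; no empirical
  data ship with the package.
* Direction-inconsistent "successful" replications.
* Corrected sequential designs (alpha-spending); peeking is modelled
  naive by design.
* Covariate hacking and other unmodelled QRPs; combining several QRPs.
* Bayesian reformulations (e.g. Bayes-factor hacking).
* The synthetic data generator emulates idealized normal (optionally
  contaminated-normal) samples with homogeneous effects — no
  heteroscedasticity, skew, clustering or publication-lag structure, so
  passing tests certify the model's internal consistency, not the
  behaviour of any particular empirical literature.
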