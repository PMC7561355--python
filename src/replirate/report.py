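"""Scenario grids: replication and false-positive rates over pi x k x d x alpha.

This module materializes the model's figure content as long-format tables.
For every grid cell it computes the strategy's effective (Type-1 error,
power), the non-hacking good-practice reference, and plugs both into the
replication-rate and false-positive-rate formulas.  The difference
RR_good - RR_hacked is the *shrinkage* of the replication rate caused by
the questionable practice; it can be negative, since power inflation
occasionally makes the hacked pipeline replicate slightly better.

Defaults mirror the canonical scenario: n = 20 per group, one-sided tests,
d in {0.2, 0.5, 0.8}, nominal alpha in {0.5%, 5%}, replication studies at
alpha2 = 0.05 with power2 = 0.90.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ScenarioParams,
    StudyDesign,
    Tails,
    TestForm,
    UndefinedRateError,
    false_positive_rate,
    replication_rate,
    ztest_rejection_prob,
)
from .outliers import OutlierRemoval, OutlierSimConfig
from .strategies import (
    FIGURE_SCHEDULE,
    DataPeeking,
    MeasureBattery,
    MultipleMeasures,
    PeekSchedule,
    SelectiveReporting,
)

__all__ = [
    "STRATEGY_NAMES",
    "GridSpec",
    "make_strategy",
    "good_practice_reference",
    "evaluate_grid",
    "write_table",
    "read_table",
]

STRATEGY_NAMES = (
    "selective-reporting",
    "multiple-measures",
    "data-peeking",
    "outlier-removal",
)

#: Deterministic column order of a RateTable.
TABLE_COLUMNS = [
    "strategy",
    "alpha1",
    "d",
    "k",
    "pi",
    "alpha_eff",
    "power_eff",
    "alpha_good",
    "power_good",
    "FPR_hacked",
    "FPR_good",
    "RR_hacked",
    "RR_good",
    "shrinkage",
    "note",
]
_SORT_KEYS = ["strategy", "alpha1", "d", "k", "pi"]


def make_strategy(
    name: str,
    *,
    alpha: float = 0.05,
    k: int = 1,
    n_per_group: int = 20,
    tails: Tails | str = Tails.ONE_SIDED,
    test_form: TestForm | str = TestForm.TWO_SAMPLE,
    rho: float = 0.2,
    schedule: PeekSchedule | Sequence[int] = FIGURE_SCHEDULE,
    contamination_rate: float = 0.05,
    contamination_sd: float = 10.0,
    n_reps: int = 10_000,
    seed: int = 0,
    mode: str = "filter_first",
):
    """Build a strategy object from its CLI-facing name and parameters.

    ``k`` means: number of studies (selective reporting), number of
    dependent measures (multiple measures), number of peeks — the first k
    looks of ``schedule`` — (data peeking), or the length of the analysis
    sequence (outlier removal).
    """
    design = StudyDesign(
        test_form=TestForm(test_form),
        n_per_group=n_per_group,
        alpha_nominal=alpha,
        tails=Tails(tails),
    )
    if name == "selective-reporting":
        return SelectiveReporting(design, k=k)
    if name == "multiple-measures":
        return MultipleMeasures(design, MeasureBattery(k=k, rho=rho))
    if name == "data-peeking":
        if not isinstance(schedule, PeekSchedule):
            schedule = PeekSchedule(schedule)
        return DataPeeking(design, schedule.truncated(k))
    if name == "outlier-removal":
        config = OutlierSimConfig(
            test_form=TestForm(test_form),
            n_per_group=n_per_group,
            alpha_nominal=alpha,
            contamination_rate=contamination_rate,
            contamination_sd=contamination_sd,
            n_reps=n_reps,
            seed=seed,
            mode=mode,
        ).truncated(k)
        return OutlierRemoval(config)
    raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}")


def good_practice_reference(strategy, d: float) -> tuple[float, float]:
    """(alpha, power) of the honest single-analysis counterpart.

    Selective reporting / multiple measures / outlier removal reduce to a
    single test (k = 1, the first analysis); data peeking to one
    preplanned test at the schedule's final sample size.  The reference
    does not depend on k, which is what makes it a fixed baseline across
    a strategy's k-sweep.
    """
    return strategy.good_practice_rates(d)


@dataclass(frozen=True)
class GridSpec:
    """A full scenario grid for one strategy."""

    strategy: str
    pi_values: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 4))
    k_values: tuple[int, ...] = (1, 2, 4, 6, 8)
    d_values: tuple[float, ...] = (0.2, 0.5, 0.8)
    alpha_values: tuple[float, ...] = (0.005, 0.05)
    alpha2: float = 0.05
    power2: float = 0.90
    strategy_kwargs: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        object.__setattr__(self, "pi_values", tuple(self.pi_values))
        object.__setattr__(self, "k_values", tuple(self.k_values))
        object.__setattr__(self, "d_values", tuple(self.d_values))
        object.__setattr__(self, "alpha_values", tuple(self.alpha_values))


def evaluate_grid(spec: GridSpec) -> pd.DataFrame:
    """Evaluate a RateTable over the grid.

    Cells whose conditional rates are undefined (0/0 corners) are kept but
    annotated in the ``note`` column with NaN rates instead of aborting
    the whole grid.
    """
    rows = []
    for alpha in spec.alpha_values:
        for k in spec.k_values:
            strat = make_strategy(spec.strategy, alpha=alpha, k=k, **spec.strategy_kwargs)
            for d in spec.d_values:
                alpha_eff, power_eff = strat.effective_rates(d)
                alpha_good, power_good = strat.good_practice_rates(d)
                for pi in spec.pi_values:
                    row = {
                        "strategy": spec.strategy,
                        "alpha1": alpha,
                        "d": d,
                        "k": k,
                        "pi": pi,
                        "alpha_eff": alpha_eff,
                        "power_eff": power_eff,
                        "alpha_good": alpha_good,
                        "power_good": power_good,
                        "note": "",
                    }
                    try:
                        row["FPR_hacked"] = false_positive_rate(pi, alpha_eff, power_eff)
                        row["FPR_good"] = false_positive_rate(pi, alpha_good, power_good)
                        row["RR_hacked"] = replication_rate(
                            ScenarioParams(pi, alpha_eff, power_eff, spec.alpha2, spec.power2)
                        )
                        row["RR_good"] = replication_rate(
                            ScenarioParams(pi, alpha_good, power_good, spec.alpha2, spec.power2)
                        )
                        row["shrinkage"] = row["RR_good"] - row["RR_hacked"]
                    except UndefinedRateError as exc:
                        for col in ("FPR_hacked", "FPR_good", "RR_hacked", "RR_good", "shrinkage"):
                            row[col] = np.nan
                        row["note"] = f"undefined: {exc}"
                    rows.append(row)
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table = table.sort_values(_SORT_KEYS, kind="mergesort").reset_index(drop=True)
    return table


def _meta_header(meta: dict | None) -> str:
    from . import __version__

    lines = [f"# replirate {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def write_table(
    table: pd.DataFrame, path: str | os.PathLike, format: str = "csv", meta: dict | None = None
) -> None:
    """Write a RateTable deterministically (sorted, 12 significant digits).

    CSV output carries ``#`` metadata header lines (package version plus
    the resolved parameter set) and round-trips losslessly through
    :func:`read_table`.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    table = table.sort_values(
        [c for c in _SORT_KEYS if c in table.columns], kind="mergesort"
    ).reset_index(drop=True)
    if format == "csv":
        buf = io.StringIO()
        buf.write(_meta_header(meta))
        table.to_csv(buf, index=False, float_format="%.12g", lineterminator="\n")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    elif format == "json":
        payload = {
            "meta": {k: str(v) for k, v in (meta or {}).items()},
            "rows": json.loads(table.to_json(orient="records", double_precision=12)),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def read_table(path: str | os.PathLike, format: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    if format == "csv":
        df = pd.read_csv(path, comment="#", keep_default_na=True)
        if "note" in df.columns:
            df["note"] = df["note"].fillna("")
        return df
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["rows"])
    raise ValueError(f"unknown format {format!r}")
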