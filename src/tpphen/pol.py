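"""Pace-of-life classification from observed development rates.

Within one rearing temperature, each life stage's rates are split at the
population median: individuals above the median are in the *upper* (fast)
category, below it in the *lower* (slow) category.  An individual that stays
in the same category for at least ``k_min`` of the scored stages (5 of 7 by
default: egg plus the six larval instars) is labelled fast or slow; everyone
else is intermediate.  Because the rule only uses ranks relative to the
median, it is invariant under monotone transforms of the rates.

Median ties are assigned to the lower category -- a deliberate, deterministic
choice that matters in practice because daily checks quantize durations and
tied rates are common.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import RearingDataset, SCORED_STAGES

UPPER = "U"
LOWER = "L"

__all__ = [
    "StageCategoryTable",
    "StrategyAssignment",
    "categorize_stagewise",
    "assign_strategies",
    "strategy_proportions",
    "write_category_table",
    "write_assignment",
]


@dataclasses.dataclass
class StageCategoryTable:
    """Per-individual, per-stage upper/lower categories at one temperature.

    ``frame`` is indexed by individual id with one column per scored stage;
    cells hold ``"U"``, ``"L"`` or ``NaN`` (stage not observed).
    """

    frame: pd.DataFrame
    temperature: float

    @property
    def stages(self) -> list[str]:
        return list(self.frame.columns)


@dataclasses.dataclass
class StrategyAssignment:
    """Individual -> slow/fast/intermediate labels with the rule's thresholds."""

    strategies: dict[str, str]
    k_min: int
    n_stages: int

    def __len__(self) -> int:
        return len(self.strategies)


def categorize_stagewise(
    dataset: RearingDataset,
    temperature: float,
    stages: Sequence[str] = SCORED_STAGES,
) -> StageCategoryTable:
    """Median-split every scored stage of one temperature's population.

    Rates strictly above the per-stage median are upper, strictly below are
    lower, and ties at the median go to lower.  The median is computed over
    all individuals observed at that stage (not only complete individuals).
    Raises if any scored stage has fewer than 2 observed individuals.
    """
    stages = list(stages)
    f = dataset.frame
    sub = f[f["mean_temp"] == float(temperature)]
    if sub.empty:
        raise ValueError(f"no observations at temperature {temperature}")
    individuals = sorted(sub["individual_id"].unique())
    table = pd.DataFrame(index=individuals, columns=stages, dtype=object)
    for stage in stages:
        cell = sub[sub["stage"] == stage]
        if len(cell) < 2:
            raise ValueError(
                f"stage {stage!r} at {temperature} °C has {len(cell)} individual(s); "
                "need >= 2 for a median split"
            )
        med = float(np.median(cell["rate"].to_numpy()))
        cats = np.where(cell["rate"].to_numpy() > med, UPPER, LOWER)
        table.loc[cell["individual_id"].to_numpy(), stage] = cats
    return StageCategoryTable(frame=table, temperature=float(temperature))


def assign_strategies(
    table: StageCategoryTable, k_min: int = 5, n_required: int | None = None
) -> StrategyAssignment:
    """Label individuals by category consistency across scored stages.

    An individual with at least ``k_min`` upper stages out of ``n_required``
    scored stages is fast, with at least ``k_min`` lower stages slow, and
    intermediate otherwise.  With ``k_min > n_required / 2`` the two
    conditions cannot both hold.  Individuals missing any scored stage are
    excluded.
    """
    if n_required is None:
        n_required = len(table.stages)
    if k_min > n_required:
        raise ValueError("k_min cannot exceed the number of scored stages")
    if len(table.stages) != n_required:
        raise ValueError(
            f"table scores {len(table.stages)} stages but n_required={n_required}"
        )
    strategies: dict[str, str] = {}
    for ind, row in table.frame.iterrows():
        if row.isna().any():
            continue
        n_upper = int((row == UPPER).sum())
        n_lower = int((row == LOWER).sum())
        if n_upper >= k_min:
            strategies[str(ind)] = "fast"
        elif n_lower >= k_min:
            strategies[str(ind)] = "slow"
        else:
            strategies[str(ind)] = "intermediate"
    return StrategyAssignment(strategies=strategies, k_min=k_min, n_stages=n_required)


def strategy_proportions(
    assignment: StrategyAssignment,
) -> tuple[float, float, float]:
    """(slow, fast, intermediate) fractions over classified individuals."""
    if not assignment.strategies:
        raise ValueError("no classified individuals")
    labels = list(assignment.strategies.values())
    n = len(labels)
    return (
        labels.count("slow") / n,
        labels.count("fast") / n,
        labels.count("intermediate") / n,
    )


def write_category_table(table: StageCategoryTable, path: str | Path) -> None:
    out = table.frame.fillna("NA")
    out.index.name = "individual_id"
    out.to_csv(path)


def write_assignment(assignment: StrategyAssignment, path: str | Path) -> None:
    rows = sorted(assignment.strategies.items())
    pd.DataFrame(rows, columns=["individual_id", "strategy"]).to_csv(path, index=False)
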