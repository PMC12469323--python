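"""Baselines and cost/accuracy comparison arithmetic.

Two reference strategies frame the variable-step search:

* the *exhaustive grid* — every multiple of the precision ``km`` in
  ``(0, bound]``, size ``floor(bound / km)``; its size is the denominator
  of the cost-reduction percentage;
* the *equal-step baseline* — a budget of ``b`` equally spaced learning
  rates ``i * bound / b``, evaluated ascending, keeping the best.

Report rows carry the reported "theoretical" variable-step counts as
metadata only: their counting convention is not recomputable, whereas the
actual evaluation counts and every percentage are.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .metrics import round_half_up
from .objectives import Objective, data_path
from .schedule import round_lr

__all__ = [
    "BudgetedGrid",
    "ComparisonRow",
    "exhaustive_grid_size",
    "reduction_percentage",
    "equal_step_best",
    "accuracy_improvement",
    "build_comparison_report",
    "build_budget_report",
    "load_reported_counts",
]


@dataclass(frozen=True)
class BudgetedGrid:
    """Equal-step grid of ``budget`` learning rates ``i * bound / budget``."""

    budget: int
    bound: float = 1.0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError(f"budget must be >= 1, got {self.budget}")
        if self.bound <= 0:
            raise ValueError(f"bound must be positive, got {self.bound}")

    @property
    def values(self) -> List[float]:
        return [round_lr(i * self.bound / self.budget) for i in range(1, self.budget + 1)]


def exhaustive_grid_size(bound: float, km: float) -> int:
    """Size of the km-spaced grid over ``(0, bound]``: ``floor(bound / km)``."""
    if not 0 < km <= bound:
        raise ValueError(f"require 0 < km <= bound, got km={km}, bound={bound}")
    return int(math.floor(round(bound / km, 10)))


def reduction_percentage(actual: int, exhaustive: int) -> float:
    """Percent of grid evaluations saved: ``(1 - actual/exhaustive) * 100``,
    half-up to 1 decimal."""
    if exhaustive <= 0:
        raise ValueError("exhaustive count must be positive")
    if actual > exhaustive:
        raise ValueError(f"actual ({actual}) exceeds exhaustive ({exhaustive})")
    return round_half_up((1 - actual / exhaustive) * 100, 1)


def equal_step_best(
    objective: Objective, budget: int, bound: float = 1.0
) -> Tuple[float, float]:
    """Evaluate the budgeted grid ascending; return (lr, accuracy) of the
    maximum, ties toward the smaller learning rate."""
    best_lr = None
    best_acc = -1.0
    for lr in BudgetedGrid(budget=budget, bound=bound).values:
        acc = float(objective(lr))
        if acc > best_acc:
            best_lr, best_acc = lr, acc
    return best_lr, best_acc


def accuracy_improvement(variable_best: float, equal_best: float) -> float:
    """Accuracy gain of the variable-step result over the equal-step
    baseline, both as percent values; half-up to 2 decimals."""
    for v in (variable_best, equal_best):
        if not 0 <= v <= 100:
            raise ValueError(f"percent value out of [0, 100]: {v}")
    return round_half_up(variable_best - equal_best, 2)


@dataclass(frozen=True)
class ComparisonRow:
    """One cost-comparison row: search interval bound, precision, counts,
    and the derived reduction percentage."""

    interval: float
    km: float
    theoretical_variable: int  # reported metadata, not recomputed
    actual_variable: int
    exhaustive: int
    reduction_pct: float


def build_comparison_report(
    counts: Sequence[Tuple[float, float, int, int]],
    csv_path: Optional[str | Path] = None,
    json_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Derive exhaustive sizes and reductions from (interval, km,
    theoretical, actual) rows; optionally write CSV/JSON."""
    rows: List[ComparisonRow] = []
    for interval, km, theoretical, actual in counts:
        exhaustive = exhaustive_grid_size(interval, km)
        rows.append(
            ComparisonRow(
                interval=float(interval),
                km=float(km),
                theoretical_variable=int(theoretical),
                actual_variable=int(actual),
                exhaustive=exhaustive,
                reduction_pct=reduction_percentage(int(actual), exhaustive),
            )
        )
    df = pd.DataFrame(
        [asdict(r) for r in rows],
        columns=[
            "interval", "km", "theoretical_variable",
            "actual_variable", "exhaustive", "reduction_pct",
        ],
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(df.to_json(orient="records", indent=2) + "\n")
    return df


def build_budget_report(
    objective: Objective,
    budgets: Sequence[int],
    variable_best: float,
    bound: float = 1.0,
    csv_path: Optional[str | Path] = None,
    json_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Equal-step vs variable-step accuracy at matched budgets.

    ``variable_best`` is the variable-step accuracy as a fraction; the
    report mirrors published percent columns:
    budget, equal_best, variable_best, improvement.
    """
    rows = []
    for b in budgets:
        _, acc = equal_step_best(objective, b, bound=bound)
        equal_pct = round_half_up(acc * 100, 2)
        variable_pct = round_half_up(variable_best * 100, 2)
        rows.append(
            {
                "budget": int(b),
                "equal_best": equal_pct,
                "variable_best": variable_pct,
                "improvement": accuracy_improvement(variable_pct, equal_pct),
            }
        )
    df = pd.DataFrame(rows, columns=["budget", "equal_best", "variable_best", "improvement"])
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(df.to_json(orient="records", indent=2) + "\n")
    return df


def load_reported_counts(name: str) -> pd.DataFrame:
    """Reported per-precision evaluation counts for a built-in fixture
    (columns: interval, km, theoretical_variable, actual_variable)."""
    with resources.as_file(data_path(f"comparison_{name}.csv")) as path:
        return pd.read_csv(path)


def load_reported_budget_table(name: str) -> pd.DataFrame:
    """Reported equal-step vs variable-step percent columns for a fixture
    (columns: budget, equal_best, variable_best)."""
    with resources.as_file(data_path(f"table12_{name}.csv")) as path:
        return pd.read_csv(path)
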