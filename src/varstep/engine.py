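"""Variable-step learning-rate search engine.

Orchestrates the coarse-to-fine search: evaluate the round-0 schedule in
ascending order, abandon a round after ``consecutive_limit`` fresh
evaluations in a row fall below ``interruption_threshold``, bracket the
best learning rate between its nearest evaluated neighbours, subdivide the
bracket, and repeat until the bracket is resolved at precision ``km``, the
accuracy target is exceeded, the bracket holds no unevaluated candidate, or
a safety round cap is hit.

Every learning rate is evaluated at most once per search: results live in
an insertion-ordered cache and cache hits are served without touching the
objective (they also leave the consecutive-failure counter untouched — the
counter models wasted training runs, and a cache hit costs nothing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .objectives import EvaluationError, Objective
from .schedule import (
    Bracket,
    SchedulePolicy,
    initial_candidates,
    refine_candidates,
    round_lr,
)

__all__ = [
    "SearchPolicy",
    "EvaluationRecord",
    "EvaluationCache",
    "RoundRecord",
    "SearchOutcome",
    "run_round",
    "select_bracket",
    "should_terminate",
    "run_search",
]

logger = logging.getLogger("varstep")


@dataclass(frozen=True)
class SearchPolicy:
    """Interruption and termination rules of the search loop."""

    interruption_threshold: float = 0.80
    consecutive_limit: int = 3
    stop_accuracy: float = 0.99
    max_rounds: int = 20
    interruption_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.interruption_threshold < self.stop_accuracy <= 1):
            raise ValueError(
                "require 0 < interruption_threshold < stop_accuracy <= 1, got "
                f"{self.interruption_threshold}, {self.stop_accuracy}"
            )
        if self.consecutive_limit < 1:
            raise ValueError(f"consecutive_limit must be >= 1, got {self.consecutive_limit}")
        if self.max_rounds < 1:
            raise ValueError(f"max_rounds must be >= 1, got {self.max_rounds}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SearchPolicy":
        return cls(**data)


@dataclass(frozen=True)
class EvaluationRecord:
    lr: float
    accuracy: float
    round_index: int
    from_cache: bool = False


class EvaluationCache:
    """Insertion-ordered map from rounded learning rate to accuracy.

    Lookups never trigger re-evaluation; one entry per rounded lr.
    """

    def __init__(self) -> None:
        self._data: Dict[float, float] = {}

    def __contains__(self, lr: float) -> bool:
        return round_lr(lr) in self._data

    def __len__(self) -> int:
        return len(self._data)

    def __getitem__(self, lr: float) -> float:
        return self._data[round_lr(lr)]

    def add(self, lr: float, accuracy: float) -> None:
        key = round_lr(lr)
        if key in self._data:
            raise ValueError(f"learning rate {key} already evaluated")
        self._data[key] = float(accuracy)

    def items(self):
        return self._data.items()

    def learning_rates(self) -> List[float]:
        return list(self._data)

    def best(self) -> EvaluationRecord:
        """Best (lr, accuracy); ties broken toward the smaller lr."""
        if not self._data:
            raise ValueError("empty evaluation cache")
        lr = min(self._data, key=lambda k: (-self._data[k], k))
        return EvaluationRecord(lr=lr, accuracy=self._data[lr], round_index=-1)


@dataclass
class RoundRecord:
    """Trace of one search round."""

    index: int
    proposed: List[float]
    evaluated: List[EvaluationRecord]        # fresh evaluations only
    cache_hits: List[EvaluationRecord]       # re-proposed, served from cache
    interrupted: bool
    bracket_used: Optional[Bracket] = None

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "proposed": self.proposed,
            "evaluated": [asdict(r) for r in self.evaluated],
            "cache_hits": [asdict(r) for r in self.cache_hits],
            "interrupted": self.interrupted,
            "bracket_used": asdict(self.bracket_used) if self.bracket_used else None,
        }


@dataclass
class SearchOutcome:
    """Aggregate result of a search: best point, cost, and full trace."""

    best_lr: float
    best_accuracy: float
    total_new_evaluations: int
    rounds: List[RoundRecord]
    termination_reason: str

    def to_dict(self) -> dict:
        return {
            "best_lr": self.best_lr,
            "best_accuracy": self.best_accuracy,
            "total_new_evaluations": self.total_new_evaluations,
            "termination_reason": self.termination_reason,
            "rounds": [r.to_dict() for r in self.rounds],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def new_lrs_per_round(self) -> List[List[float]]:
        """Ordered list of freshly evaluated learning rates, per round."""
        return [[r.lr for r in rnd.evaluated] for rnd in self.rounds]

    def trace_dataframe(self) -> pd.DataFrame:
        """Flat trace: one row per visited candidate (fresh or cached)."""
        rows = []
        for rnd in self.rounds:
            for rec in sorted(
                rnd.evaluated + rnd.cache_hits, key=lambda r: rnd.proposed.index(r.lr)
            ):
                rows.append(
                    {
                        "round": rnd.index,
                        "lr": rec.lr,
                        "accuracy": rec.accuracy,
                        "from_cache": rec.from_cache,
                        "interrupted_round": rnd.interrupted,
                    }
                )
        return pd.DataFrame(
            rows, columns=["round", "lr", "accuracy", "from_cache", "interrupted_round"]
        )

    def to_trace_csv(self, path: str | Path) -> None:
        self.trace_dataframe().to_csv(path, index=False)


def run_round(
    candidates: Sequence[float],
    objective: Objective,
    cache: EvaluationCache,
    policy: SearchPolicy,
    round_index: int = 0,
    bracket: Optional[Bracket] = None,
) -> RoundRecord:
    """Evaluate ``candidates`` in ascending order under the interruption rule.

    Cached learning rates are skipped (no objective call, failure counter
    unaffected).  Fresh accuracies below ``interruption_threshold`` advance
    a consecutive-failure counter that any success resets; reaching
    ``consecutive_limit`` abandons the remaining candidates for this round.
    """
    proposed = [round_lr(c) for c in candidates]
    if proposed != sorted(proposed):
        raise ValueError("candidates must be ascending")

    evaluated: List[EvaluationRecord] = []
    hits: List[EvaluationRecord] = []
    consecutive = 0
    interrupted = False

    for lr in proposed:
        if lr in cache:
            hits.append(
                EvaluationRecord(lr=lr, accuracy=cache[lr], round_index=round_index,
                                 from_cache=True)
            )
            logger.info("round=%d lr=%g accuracy=%.4f cache_hit", round_index, lr, cache[lr])
            continue
        try:
            accuracy = float(objective(lr))
        except Exception as exc:
            raise EvaluationError(
                f"objective evaluation failed at learning rate {lr}: {exc}"
            ) from exc
        cache.add(lr, accuracy)
        evaluated.append(
            EvaluationRecord(lr=lr, accuracy=accuracy, round_index=round_index)
        )
        logger.info("round=%d lr=%g accuracy=%.4f", round_index, lr, accuracy)
        if policy.interruption_enabled:
            if accuracy < policy.interruption_threshold:
                consecutive += 1
                if consecutive >= policy.consecutive_limit:
                    interrupted = True
                    logger.info(
                        "round=%d interrupted after %d consecutive accuracies < %.2f",
                        round_index, consecutive, policy.interruption_threshold,
                    )
                    break
            else:
                consecutive = 0

    return RoundRecord(
        index=round_index,
        proposed=proposed,
        evaluated=evaluated,
        cache_hits=hits,
        interrupted=interrupted,
        bracket_used=bracket,
    )


def select_bracket(cache: EvaluationCache, schedule: SchedulePolicy) -> Bracket:
    """Bracket the best cached learning rate between its evaluated neighbours.

    Falls back to ``[lower_bound, k2]`` at the boundary of the evaluated
    set when a side has no neighbour.
    """
    best = cache.best()
    lrs = cache.learning_rates()
    below = [lr for lr in lrs if lr < best.lr]
    above = [lr for lr in lrs if lr > best.lr]
    lrl = max(below) if below else schedule.lower_bound
    lrr = min(above) if above else schedule.k2
    # lower_bound fallback can exceed lrb when the best sits below it
    lrl = min(lrl, best.lr)
    lrr = max(lrr, best.lr)
    return Bracket(lrl=lrl, lrb=best.lr, lrr=lrr)


def should_terminate(
    cache: EvaluationCache,
    bracket: Bracket,
    new_candidates: Sequence[float],
    schedule: SchedulePolicy,
    policy: SearchPolicy,
    rounds_completed: int,
) -> Optional[str]:
    """Termination decision after a round; ``None`` means keep searching.

    Checked in order: accuracy target exceeded; bracket exhausted (no
    unevaluated candidate left — the search has taken every value in the
    interval); bracket already resolved at precision ``km``; safety round
    cap.
    """
    if cache.best().accuracy > policy.stop_accuracy:
        return "accuracy_target"
    if all(c in cache for c in new_candidates):
        return "exhausted"
    if max(bracket.left_gap, bracket.right_gap) <= round_lr(schedule.km):
        return "interval_le_km"
    if rounds_completed >= policy.max_rounds:
        return "max_rounds"
    return None


def run_search(
    objective: Objective,
    schedule: SchedulePolicy,
    policy: SearchPolicy | None = None,
) -> SearchOutcome:
    """Run the full variable-step search and return outcome plus trace.

    Round 0 evaluates the combined coarse schedule; each later round
    subdivides the bracket around the current best.  The engine draws no
    randomness of its own.
    """
    policy = policy or SearchPolicy()
    cache = EvaluationCache()
    rounds: List[RoundRecord] = []

    candidates = initial_candidates(schedule)
    bracket: Optional[Bracket] = None
    reason = "max_rounds"

    for round_index in range(policy.max_rounds + 1):
        record = run_round(candidates, objective, cache, policy, round_index, bracket)
        rounds.append(record)

        bracket = select_bracket(cache, schedule)
        candidates = refine_candidates(bracket, schedule)
        decision = should_terminate(
            cache, bracket, candidates, schedule, policy, rounds_completed=len(rounds)
        )
        if decision is not None:
            reason = decision
            break

    best = cache.best()
    if reason == "max_rounds":
        logger.warning("search stopped by max_rounds=%d safety cap", policy.max_rounds)
    logger.info(
        "search done: best_lr=%g best_accuracy=%.4f evaluations=%d reason=%s",
        best.lr, best.accuracy, len(cache), reason,
    )
    return SearchOutcome(
        best_lr=best.lr,
        best_accuracy=best.accuracy,
        total_new_evaluations=len(cache),
        rounds=rounds,
        termination_reason=reason,
    )
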