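"""Candidate learning-rate schedules for the variable-step search.

The search variable is a single learning rate in ``(0, k2]`` (by default
``(0, 1]``).  Round 0 ("large-interval fast positioning") mixes log-spaced
candidates ``k2 / 10**n`` inside the conventional experience interval
``[lower_bound, k1]`` with an equal-step ladder ``m * (k2 - k1) / p`` above
it.  Later rounds ("inter-cell precise optimization") subdivide the bracket
around the current best learning rate with a gap-dependent step: the fine
precision ``km`` once a gap is small enough to be resolved by it, otherwise
one ``p``-th of the gap.

All learning rates are identified after rounding to 10 decimal places so
that repeated float addition (``0.001 + 0.005``) lands exactly on the value
a table or cache key expects.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Sequence

import yaml

__all__ = [
    "LR_DECIMALS",
    "round_lr",
    "SchedulePolicy",
    "Bracket",
    "small_step_candidates",
    "equal_step_candidates",
    "initial_candidates",
    "refinement_step",
    "refine_candidates",
]

#: Number of decimal places that define learning-rate identity.
LR_DECIMALS = 10


def round_lr(lr: float) -> float:
    """Canonical learning-rate value: rounded to :data:`LR_DECIMALS` places."""
    return round(float(lr), LR_DECIMALS)


@dataclass(frozen=True)
class SchedulePolicy:
    """Constants of the candidate-generation rules.

    Parameters
    ----------
    km : float
        Learning-rate precision — the finest resolution at which two
        learning rates are considered distinct, and the fine refinement
        step.
    k1 : float
        Upper bound of the conventional "experience" interval (default 0.1);
        log-spaced candidates live at or below it.
    k2 : float
        Upper bound of the overall search interval (default 1.0).
    p : int
        Subdivision divisor for coarse steps (default 9).
    n_min, n_max : int
        Exponent range of the log-spaced rule ``k2 / 10**n``.
    m_min, m_max : int
        Multiplier range of the equal-step rule ``m * s1``.
    lower_bound : float
        Smallest admissible learning rate (default ``1e-5``).
    """

    km: float
    k1: float = 0.1
    k2: float = 1.0
    p: int = 9
    n_min: int = 1
    n_max: int = 5
    m_min: int = 2
    m_max: int = 10
    lower_bound: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.lower_bound < self.k1 < self.k2):
            raise ValueError(
                "require 0 < lower_bound < k1 < k2, got "
                f"lower_bound={self.lower_bound}, k1={self.k1}, k2={self.k2}"
            )
        if not (0 < self.km < self.k1):
            raise ValueError(f"require 0 < km < k1, got km={self.km}, k1={self.k1}")
        if not (isinstance(self.p, int) and self.p >= 1):
            raise ValueError(f"p must be a positive integer, got {self.p!r}")
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError(f"require 1 <= n_min <= n_max, got {self.n_min}, {self.n_max}")
        if not (2 <= self.m_min <= self.m_max):
            raise ValueError(f"require 2 <= m_min <= m_max, got {self.m_min}, {self.m_max}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SchedulePolicy":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SchedulePolicy":
        return cls.from_dict(_load_config_file(path))

    def to_file(self, path: str | Path) -> None:
        _dump_config_file(self.to_dict(), path)


@dataclass(frozen=True)
class Bracket:
    """Refinement region around the current best learning rate.

    ``lrb`` is the benchmark (best so far); ``lrl`` and ``lrr`` are its
    nearest evaluated neighbours on each side (or the interval boundaries
    when no neighbour exists).
    """

    lrl: float
    lrb: float
    lrr: float

    def __post_init__(self) -> None:
        if not (self.lrl <= self.lrb <= self.lrr):
            raise ValueError(f"bracket not ordered: {self.lrl}, {self.lrb}, {self.lrr}")

    @property
    def left_gap(self) -> float:
        return round_lr(self.lrb - self.lrl)

    @property
    def right_gap(self) -> float:
        return round_lr(self.lrr - self.lrb)


def _load_config_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_config_file(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _ascending_unique(values: Sequence[float]) -> List[float]:
    return sorted({round_lr(v) for v in values})


def small_step_candidates(policy: SchedulePolicy) -> List[float]:
    """Log-spaced candidates ``k2 / 10**n`` for ``n = n_min .. n_max``.

    With the defaults this is ``{1e-5, 1e-4, 1e-3, 0.01, 0.1}`` — variable
    amplitude, small step, covering the experience interval.
    """
    return _ascending_unique(
        policy.k2 / 10**n for n in range(policy.n_min, policy.n_max + 1)
    )


def equal_step_candidates(policy: SchedulePolicy) -> List[float]:
    """Equal-step candidates ``m * s1`` with ``s1 = (k2 - k1) / p``.

    With the defaults ``s1 = 0.1`` and the ladder is ``{0.2, 0.3, ..., 1.0}``.
    """
    s1 = round_lr((policy.k2 - policy.k1) / policy.p)
    return _ascending_unique(m * s1 for m in range(policy.m_min, policy.m_max + 1))


def initial_candidates(policy: SchedulePolicy) -> List[float]:
    """Round-0 schedule: union of the log-spaced and equal-step rules."""
    return _ascending_unique(small_step_candidates(policy) + equal_step_candidates(policy))


def refinement_step(gap: float, km: float, p: int) -> float:
    """Step size used to subdivide one side of a bracket.

    Returns ``km`` when the gap can be resolved at the target precision
    (``gap <= 10 * km``, the tie going to the fine branch), else ``gap / p``.
    """
    if gap < 0:
        raise ValueError(f"gap must be nonnegative, got {gap}")
    if km <= 0:
        raise ValueError(f"km must be positive, got {km}")
    gap = round_lr(gap)
    if gap <= round_lr(10 * km):
        return round_lr(km)
    return round_lr(gap / p)


def refine_candidates(bracket: Bracket, policy: SchedulePolicy) -> List[float]:
    """Candidates subdividing both sides of ``bracket``.

    Left side: ``lrl + j * s2_left`` strictly below the benchmark.
    Right side: ``lrb + j * s2_right`` up to and including ``lrr``.
    The two sequences are merged into one ascending, duplicate-free list;
    filtering out already-evaluated values is the engine's job.
    An empty result is legal (both gaps smaller than one step).
    """
    out: List[float] = []

    if bracket.left_gap > 0:
        step = refinement_step(bracket.left_gap, policy.km, policy.p)
        j = 1
        while True:
            value = round_lr(bracket.lrl + j * step)
            if value >= bracket.lrb:
                break
            out.append(value)
            j += 1

    if bracket.right_gap > 0:
        step = refinement_step(bracket.right_gap, policy.km, policy.p)
        j = 1
        while True:
            value = round_lr(bracket.lrb + j * step)
            if value > bracket.lrr:
                break
            out.append(value)
            j += 1

    return _ascending_unique(out)
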