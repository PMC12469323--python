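"""Objective functions mapping a learning rate to a validation accuracy.

The search engine treats model training as a black box: an objective is any
callable ``lr -> accuracy`` (a fraction in ``[0, 1]``) that is total over
its declared domain and deterministic for a fixed configuration.  Two
implementations are provided:

* :class:`TabulatedObjective` — exact replay of a printed
  (learning rate, accuracy) table, such as the fish-classifier tuning runs
  shipped as built-in fixtures (ResNet18, ShuffleNet, EfficientNet,
  MobileNetV3, YOLOv8 validation accuracies).
* :class:`SyntheticObjective` — a seeded accuracy-response surface, a
  Gaussian bump in log10(learning rate) over a floor, emulating the broad
  single-optimum shape such tuning curves show in practice.

Accuracies are stored as fractions everywhere (96.33% -> 0.9633); percent
formatting happens only at I/O boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .schedule import round_lr

__all__ = [
    "Objective",
    "EvaluationError",
    "TabulatedObjective",
    "SyntheticObjectiveSpec",
    "SyntheticObjective",
    "make_tabulated",
    "make_synthetic",
    "builtin_fixtures",
    "FIXTURE_NAMES",
    "data_path",
]

#: Built-in tabulated fixtures (one per tuned classifier).
FIXTURE_NAMES = ("resnet18", "shufflenet", "efficientnet", "mobilenetv3", "yolov8")

Objective = Callable[[float], float]


class EvaluationError(KeyError):
    """Raised when an objective cannot produce a value for a learning rate."""


def data_path(name: str):
    """Path-like handle to a packaged data file."""
    return resources.files("varstep") / "data" / name


class TabulatedObjective:
    """Replay objective backed by a fixed (lr, accuracy) table.

    Parameters
    ----------
    records : iterable of (lr, accuracy)
        Accuracies as fractions in [0, 1]; lrs unique after rounding.
    missing_policy : {"error", "nearest"}
        ``error`` raises :class:`EvaluationError` for an absent lr (turning
        any deviation from a recorded search trajectory into a loud
        failure); ``nearest`` returns the accuracy of the closest stored lr,
        ties going to the smaller one.
    """

    def __init__(
        self,
        records: Iterable[Tuple[float, float]],
        missing_policy: str = "error",
        name: str = "tabulated",
    ):
        if missing_policy not in ("error", "nearest"):
            raise ValueError(f"unknown missing_policy: {missing_policy!r}")
        table: Dict[float, float] = {}
        for lr, acc in records:
            key = round_lr(lr)
            if key in table:
                raise ValueError(f"duplicate learning rate after rounding: {key}")
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy out of [0, 1] at lr={key}: {acc}")
            table[key] = float(acc)
        if not table:
            raise ValueError("empty objective table")
        self.table = dict(sorted(table.items()))
        self.missing_policy = missing_policy
        self.name = name

    def __call__(self, lr: float) -> float:
        key = round_lr(lr)
        if key in self.table:
            return self.table[key]
        if self.missing_policy == "nearest":
            nearest = min(self.table, key=lambda k: (abs(k - key), k))
            return self.table[nearest]
        raise EvaluationError(f"no tabulated accuracy for learning rate {key}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path, missing_policy: str = "error", name: str | None = None):
        df = pd.read_csv(path)
        if not {"lr", "accuracy"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns lr,accuracy")
        return cls(
            zip(df["lr"], df["accuracy"]),
            missing_policy=missing_policy,
            name=name or Path(str(path)).stem,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"lr": list(self.table), "accuracy": list(self.table.values())}
        ).to_csv(path, index=False)


def make_tabulated(
    records: Iterable[Tuple[float, float]],
    missing_policy: str = "error",
    name: str = "tabulated",
) -> TabulatedObjective:
    """Build a replay objective from (lr, accuracy) records."""
    return TabulatedObjective(records, missing_policy=missing_policy, name=name)


@dataclass(frozen=True)
class SyntheticObjectiveSpec:
    """Parameters of a synthetic accuracy-response surface.

    ``accuracy(lr) = clamp(floor_acc + (peak_acc - floor_acc) *
    exp(-(log10 lr - log10 peak_lr)^2 / (2 * log_width^2)) + eps, 0, 1)``
    with ``eps`` a zero-mean Gaussian draw of sd ``noise_sd``, frozen per
    distinct learning rate so repeated queries agree.
    """

    peak_lr: float
    peak_acc: float = 0.96
    floor_acc: float = 0.45
    log_width: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.peak_lr <= 1:
            raise ValueError(f"peak_lr must be in (0, 1], got {self.peak_lr}")
        if not self.floor_acc < self.peak_acc <= 1:
            raise ValueError(
                f"require floor_acc < peak_acc <= 1, got {self.floor_acc}, {self.peak_acc}"
            )
        if self.log_width <= 0:
            raise ValueError(f"log_width must be positive, got {self.log_width}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticObjectiveSpec":
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "SyntheticObjectiveSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


class SyntheticObjective:
    """Seeded synthetic objective; see :class:`SyntheticObjectiveSpec`.

    Noise is a frozen random field over learning rates: each distinct
    (rounded) lr gets its own deterministic draw derived from the spec seed,
    independent of query order, and the value is cached for the lifetime of
    the objective.
    """

    def __init__(self, spec: SyntheticObjectiveSpec):
        self.spec = spec
        self.name = f"synthetic(peak_lr={spec.peak_lr})"
        self._noise_cache: Dict[float, float] = {}

    def _noise(self, key: float) -> float:
        if self.spec.noise_sd == 0:
            return 0.0
        if key not in self._noise_cache:
            # per-lr substream: order-independent determinism
            rng = np.random.default_rng([self.spec.seed, int(round(key * 1e10))])
            self._noise_cache[key] = float(rng.normal(0.0, self.spec.noise_sd))
        return self._noise_cache[key]

    def __call__(self, lr: float) -> float:
        key = round_lr(lr)
        if key <= 0:
            raise EvaluationError(f"learning rate must be positive, got {key}")
        s = self.spec
        z = (math.log10(key) - math.log10(s.peak_lr)) / s.log_width
        value = s.floor_acc + (s.peak_acc - s.floor_acc) * math.exp(-0.5 * z * z)
        return min(1.0, max(0.0, value + self._noise(key)))


def make_synthetic(spec: SyntheticObjectiveSpec) -> SyntheticObjective:
    """Build a seeded synthetic accuracy surface from its spec."""
    return SyntheticObjective(spec)


def builtin_fixtures(missing_policy: str = "error") -> Dict[str, TabulatedObjective]:
    """The five shipped tabulated objectives, keyed by classifier name.

    Each contains exactly the recorded (learning rate, validation accuracy)
    pairs of the corresponding tuning run; learning rates that were never
    evaluated (abandoned after an interruption) are absent keys.
    """
    out: Dict[str, TabulatedObjective] = {}
    for name in FIXTURE_NAMES:
        with resources.as_file(data_path(f"{name}.csv")) as path:
            out[name] = TabulatedObjective.from_csv(
                path, missing_policy=missing_policy, name=name
            )
    return out


def load_fixture(name: str, missing_policy: str = "error") -> TabulatedObjective:
    """Load one built-in tabulated objective by name."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    with resources.as_file(data_path(f"{name}.csv")) as path:
        return TabulatedObjective.from_csv(path, missing_policy=missing_policy, name=name)
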