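"""Simulation of two-arm parallel trials with controllable selection bias.

Each simulated trial mirrors a spreadsheet with four parallel columns:
subject ID, allocation (A/B from permuted-block randomisation, block size
4), a baseline covariate drawn from a uniform distribution and listed in
ascending order, and a binary outcome that is a pure function of the
baseline (failure iff the baseline exceeds a threshold, so the covariate
is maximally prognostic).

Selection bias is injected by forcing the ``k`` lowest baseline values
into arm A before the remaining values are matched to the allocation
column; ``k`` is the bias severity (number of subverted allocations).

Two assignment schemes are supported for the non-forced values:

``"sequential"`` (default)
    The ascending value list is matched positionally against the
    allocation column, the way a spreadsheet sort by the allocation
    column pairs the two columns.  Because every block of four
    consecutive order statistics is split two/two between the arms,
    unbiased arms are balanced far more tightly than under simple
    randomisation and baseline tests essentially never reject by chance.

``"shuffled"``
    Values are paired with subjects by a uniform random permutation,
    i.e. simple random assignment.  Under this scheme a nominal-level
    baseline test has its textbook ~5% type-I error rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "StudyConfig",
    "Trial",
    "generate_allocation",
    "generate_baseline_values",
    "assign_outcomes",
    "build_unbiased_trial",
    "build_biased_trial",
    "simulate_study",
    "trials_to_frame",
    "trials_from_frame",
]

TRIAL_COLUMNS = ["trial_id", "subject_id", "arm", "baseline", "outcome", "truth", "severity_k"]

_ASSIGNMENTS = ("sequential", "shuffled")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one simulation study (defaults reproduce the published protocol).

    ``n_biased`` must equal ``len(severity_values) * trials_per_severity``;
    the biased trials come first in the study, in severity order.
    """

    n_per_arm: int = 100
    n_trials: int = 100
    n_biased: int = 50
    baseline_low: float = 1.00
    baseline_high: float = 4.50
    baseline_decimals: int = 2
    outcome_threshold: float = 2.00
    block_size: int = 4
    severity_values: tuple[int, ...] = tuple(range(33, 43))
    trials_per_severity: int = 5
    assignment: str = "sequential"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "severity_values", tuple(int(k) for k in self.severity_values))
        if self.n_biased != len(self.severity_values) * self.trials_per_severity:
            raise InvalidConfigError(
                f"n_biased={self.n_biased} != |severity_values| x trials_per_severity "
                f"= {len(self.severity_values) * self.trials_per_severity}"
            )
        if self.n_biased > self.n_trials:
            raise InvalidConfigError("n_biased exceeds n_trials")
        if not (self.baseline_low < self.outcome_threshold < self.baseline_high):
            raise InvalidConfigError("require baseline_low < outcome_threshold < baseline_high")
        if self.block_size % 2 != 0 or self.block_size < 2:
            raise InvalidConfigError("block_size must be a positive even number")
        if (2 * self.n_per_arm) % self.block_size != 0:
            raise InvalidConfigError("2*n_per_arm must be divisible by block_size")
        if any(k < 0 or k > self.n_per_arm for k in self.severity_values):
            raise InvalidConfigError("severity values must lie in [0, n_per_arm]")
        if self.assignment not in _ASSIGNMENTS:
            raise InvalidConfigError(f"assignment must be one of {_ASSIGNMENTS}")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["severity_values"] = list(self.severity_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load a config from YAML or JSON (decided by extension)."""
        text = open(path, encoding="utf-8").read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class Trial:
    """One simulated two-arm trial plus its ground-truth bias label."""

    trial_id: str
    subject_id: np.ndarray
    arm: np.ndarray
    baseline: np.ndarray
    outcome: np.ndarray
    truth: str  # "biased" | "unbiased"
    severity_k: int | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_id)
        if not (len(self.arm) == len(self.baseline) == len(self.outcome) == n):
            raise InvalidInputError("trial columns must have equal length")
        if self.truth not in ("biased", "unbiased"):
            raise InvalidInputError("truth must be 'biased' or 'unbiased'")

    def arm_baselines(self, arm: str) -> np.ndarray:
        return self.baseline[self.arm == arm]

    def arm_outcomes(self, arm: str) -> np.ndarray:
        return self.outcome[self.arm == arm]

    @property
    def n_per_arm(self) -> int:
        return int((self.arm == "A").sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "subject_id": self.subject_id,
                "arm": self.arm,
                "baseline": self.baseline,
                "outcome": self.outcome,
                "truth": self.truth,
                "severity_k": -1 if self.severity_k is None else self.severity_k,
            }
        )


def _rounded(values: np.ndarray, decimals: int) -> np.ndarray:
    """Round half away from zero (spreadsheet-style), not to even."""
    scale = 10.0**decimals
    return np.sign(values) * np.floor(np.abs(values) * scale + 0.5) / scale


def generate_allocation(n_subjects: int, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Permuted-block allocation sequence of 'A'/'B' labels.

    Each block of ``block_size`` consecutive subjects is an independent
    uniform draw over the balanced arrangements, so running balance never
    drifts by more than half a block.
    """
    if block_size % 2 != 0 or block_size < 2:
        raise InvalidConfigError("block_size must be a positive even number")
    if n_subjects % block_size != 0:
        raise InvalidConfigError(
            f"n_subjects={n_subjects} not divisible by block_size={block_size}"
        )
    base = np.array(["A"] * (block_size // 2) + ["B"] * (block_size // 2))
    blocks = [rng.permutation(base) for _ in range(n_subjects // block_size)]
    return np.concatenate(blocks)


def generate_baseline_values(
    n: int,
    low: float,
    high: float,
    decimals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """i.i.d. uniform draws on [low, high], rounded, sorted ascending.

    Duplicates are permitted; rounding happens at generation time and the
    rounded values are treated as exact thereafter.
    """
    if low >= high:
        raise InvalidConfigError(f"require low < high, got [{low}, {high}]")
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    values = _rounded(rng.uniform(low, high, size=n), decimals)
    values.sort()
    return values


def assign_outcomes(baselines: Iterable[float], threshold: float) -> np.ndarray:
    """Binary outcome per subject: 0 = success iff baseline <= threshold, else 1."""
    b = np.asarray(list(baselines) if not isinstance(baselines, np.ndarray) else baselines)
    return (b > threshold).astype(np.int8)


def _paired_values(
    allocation: np.ndarray,
    baselines: np.ndarray,
    k: int,
    assignment: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign the ascending value list to subjects; force the k lowest into arm A."""
    n = len(allocation)
    n_a = int((allocation == "A").sum())
    if k > n_a:
        raise InvalidConfigError(f"severity k={k} exceeds arm size {n_a}")
    if assignment not in _ASSIGNMENTS:
        raise InvalidConfigError(f"assignment must be one of {_ASSIGNMENTS}")
    values = np.empty(n, dtype=float)
    if k > 0:
        forced = np.flatnonzero(allocation == "A")[:k]
        free = np.setdiff1d(np.arange(n), forced, assume_unique=True)
        values[forced] = baselines[:k]
        rest = baselines[k:]
    else:
        free = np.arange(n)
        rest = baselines
    if assignment == "shuffled":
        rest = rng.permutation(rest)
    values[free] = rest
    return values


def build_unbiased_trial(
    allocation: np.ndarray,
    baselines: np.ndarray,
    rng: np.random.Generator,
    *,
    threshold: float = 2.00,
    assignment: str = "sequential",
    trial_id: str = "unbiased",
) -> Trial:
    """Trial with no subversion: values paired with subjects per ``assignment``."""
    allocation = np.asarray(allocation)
    baselines = np.asarray(baselines, dtype=float)
    if len(allocation) != len(baselines):
        raise InvalidInputError(
            f"allocation length {len(allocation)} != baselines length {len(baselines)}"
        )
    values = _paired_values(allocation, baselines, 0, assignment, rng)
    return Trial(
        trial_id=trial_id,
        subject_id=np.arange(1, len(allocation) + 1),
        arm=allocation,
        baseline=values,
        outcome=assign_outcomes(values, threshold),
        truth="unbiased",
    )


def build_biased_trial(
    allocation: np.ndarray,
    baselines_ascending: np.ndarray,
    k: int,
    rng: np.random.Generator,
    *,
    threshold: float = 2.00,
    assignment: str = "sequential",
    trial_id: str = "biased",
) -> Trial:
    """Trial whose allocation was subverted for the ``k`` lowest-baseline subjects.

    The ``k`` smallest values occupy the first ``k`` arm-A slots of the
    allocation sequence; the remaining values fill the remaining slots
    per ``assignment``.
    """
    allocation = np.asarray(allocation)
    baselines = np.asarray(baselines_ascending, dtype=float)
    if len(allocation) != len(baselines):
        raise InvalidInputError("allocation and baseline lengths differ")
    if np.any(np.diff(baselines) < 0):
        raise InvalidInputError("baselines must be sorted ascending")
    values = _paired_values(allocation, baselines, int(k), assignment, rng)
    return Trial(
        trial_id=trial_id,
        subject_id=np.arange(1, len(allocation) + 1),
        arm=allocation,
        baseline=values,
        outcome=assign_outcomes(values, threshold),
        truth="biased" if k > 0 else "unbiased",
        severity_k=int(k) if k > 0 else None,
    )


def _trial_rng(seed: int, index: int) -> np.random.Generator:
    """Independently reproducible substream for trial ``index``."""
    return np.random.default_rng([seed, index])


def simulate_study(config: StudyConfig) -> list[Trial]:
    """Generate the full study: biased trials first (severity order), then unbiased.

    Allocation sequences and baseline draws are fresh for every trial;
    everything is reproducible from ``config.seed``.
    """
    severities = [k for k in config.severity_values for _ in range(config.trials_per_severity)]
    trials: list[Trial] = []
    n_subjects = 2 * config.n_per_arm
    for i in range(config.n_trials):
        rng = _trial_rng(config.seed, i)
        allocation = generate_allocation(n_subjects, config.block_size, rng)
        baselines = generate_baseline_values(
            n_subjects, config.baseline_low, config.baseline_high, config.baseline_decimals, rng
        )
        tid = f"T{i + 1:03d}"
        if i < config.n_biased:
            trial = build_biased_trial(
                allocation,
                baselines,
                severities[i],
                rng,
                threshold=config.outcome_threshold,
                assignment=config.assignment,
                trial_id=tid,
            )
        else:
            trial = build_unbiased_trial(
                allocation,
                baselines,
                rng,
                threshold=config.outcome_threshold,
                assignment=config.assignment,
                trial_id=tid,
            )
        trials.append(trial)
    return trials


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Long-format table of all subjects of all trials (CSV-ready)."""
    return pd.concat([t.to_frame() for t in trials], ignore_index=True)


def trials_from_frame(frame: pd.DataFrame) -> list[Trial]:
    """Inverse of :func:`trials_to_frame` (severity_k = -1 encodes 'absent')."""
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    trials = []
    for tid, g in frame.groupby("trial_id", sort=False):
        k = int(g["severity_k"].iloc[0])
        trials.append(
            Trial(
                trial_id=str(tid),
                subject_id=g["subject_id"].to_numpy(),
                arm=g["arm"].to_numpy(),
                baseline=g["baseline"].to_numpy(dtype=float),
                outcome=g["outcome"].to_numpy(dtype=np.int8),
                truth=str(g["truth"].iloc[0]),
                severity_k=None if k < 0 else k,
            )
        )
    return trials
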