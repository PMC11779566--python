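"""Small deterministic fixtures with independently derived expected values.

Fixtures embed literal value lists (never seeds), so their payloads are
identical under any random-number implementation.  Each ``expected``
entry was computed by direct arithmetic on the literal payload
(provenance "derived") or is immediate from construction ("trivial");
no expected value is invented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .trial_sim import StudyConfig, Trial, assign_outcomes

__all__ = ["Fixture", "make_fixture", "list_fixtures", "write_fixture_csv", "read_fixture_csv"]


@dataclass(frozen=True)
class Fixture:
    name: str
    kind: str  # "trial" | "meta" | "study"
    payload: object
    expected: dict = field(default_factory=dict)


def _grid_values(n: int = 200, low: float = 1.00, high: float = 3.00) -> list[float]:
    """Evenly spaced grid on [low, high], rounded half away from zero to 2dp."""
    step = (high - low) / (n - 1)
    return [math.floor((low + step * i) * 100 + 0.5) / 100 for i in range(n)]


def _sequential_biased_trial(values, allocation, k, threshold, name) -> Trial:
    """Deterministic bias injection on literal data: k lowest into the
    first k A-slots, remaining ascending values positionally into the rest."""
    n = len(allocation)
    a_slots = [i for i, s in enumerate(allocation) if s == "A"]
    forced = set(a_slots[:k])
    baseline = [None] * n
    for i, v in zip(sorted(forced), values[:k]):
        baseline[i] = v
    rest = iter(values[k:])
    for i in range(n):
        if baseline[i] is None:
            baseline[i] = next(rest)
    baseline = np.array(baseline, dtype=float)
    return Trial(
        trial_id=name,
        subject_id=np.arange(1, n + 1),
        arm=np.array(allocation),
        baseline=baseline,
        outcome=assign_outcomes(baseline, threshold),
        truth="biased" if k else "unbiased",
        severity_k=k or None,
    )


def _identical_arms() -> Fixture:
    values = [1.20, 1.80, 2.40, 3.00]
    baseline = np.array(values * 2, dtype=float)
    trial = Trial(
        trial_id="identical_arms",
        subject_id=np.arange(1, 9),
        arm=np.array(["A"] * 4 + ["B"] * 4),
        baseline=baseline,
        outcome=assign_outcomes(baseline, 2.00),
        truth="unbiased",
    )
    return Fixture(
        name="identical_arms",
        kind="trial",
        payload=trial,
        expected={
            "md": (0.0, "trivial: identical arms"),
            "md_p": (1.0, "trivial: z = 0"),
            "sig_flagged": (False, "trivial"),
            "i2_flagged": (False, "trivial: trial MD equals null comparator MDs"),
            "failures_per_arm": (2, "trivial: values 2.40, 3.00 exceed 2.00"),
        },
    )


def _k39_extreme() -> Fixture:
    # 200-point even grid on [1.00, 4.50]; allocation blocks ABBA x50; k = 39.
    values = _grid_values(200, 1.00, 4.50)
    allocation = ["A", "B", "B", "A"] * 50
    trial = _sequential_biased_trial(values, allocation, 39, 2.00, "k39_extreme")
    # Expected values: direct arithmetic on the literal grid (derived).
    return Fixture(
        name="k39_extreme",
        kind="trial",
        payload=trial,
        expected={
            "mean_a": (2.6165, "derived"),
            "mean_b": (2.8835, "derived"),
            "sd_a": (1.146259067, "derived"),
            "sd_b": (0.8560449047, "derived"),
            "rd": (-0.20, "derived: 61/100 vs 81/100 failures"),
            "rd_se": (0.06259392942, "derived"),
            "rd_p": (0.00139735, "derived"),
            "rd_significant_favour_a": (True, "derived: |z| = 3.195"),
            "md": (-0.267, "derived"),
            "md_se": (0.1430637175, "derived"),
            "md_p": (0.0619992, "derived"),
            "sig_flagged": (False, "derived: p = 0.062 >= 0.05"),
            "i2_at_600": (37.8063, "derived: three-study Q = 3.21576, df = 2"),
            "i2_flagged": (True, "derived: I2 > 0 at every comparator size"),
        },
    )


def _q2_meta() -> Fixture:
    # two MD estimates theta = {0, 2}, se = {1, 1}
    payload = [(0.0, 1.0), (2.0, 1.0)]
    return Fixture(
        name="q2_meta",
        kind="meta",
        payload=payload,
        expected={
            "pooled": (1.0, "derived: equal weights"),
            "Q": (2.0, "derived: 1*(0-1)^2 + 1*(2-1)^2"),
            "df": (1, "trivial"),
            "i2_percent": (50.0, "derived: 100*(2-1)/2"),
            "pooled_se": (1.0 / math.sqrt(2.0), "derived: 1/sqrt(2)"),
        },
    )


def _mini_study() -> Fixture:
    config = StudyConfig(
        n_per_arm=10,
        n_trials=4,
        n_biased=2,
        severity_values=(6,),
        trials_per_severity=2,
        seed=123,
    )
    return Fixture(
        name="mini_study",
        kind="study",
        payload=config,
        expected={
            "n_trials": (4, "trivial"),
            "n_biased": (2, "trivial"),
            "subjects_per_trial": (20, "trivial"),
        },
    )


_REGISTRY = {
    "identical_arms": _identical_arms,
    "k39_extreme": _k39_extreme,
    "q2_meta": _q2_meta,
    "mini_study": _mini_study,
}


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str) -> Fixture:
    """Build a registered fixture; payloads are deterministic literals."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown fixture {name!r}; known: {list_fixtures()}"
        ) from None
    return factory()


def write_fixture_csv(fixture: Fixture, path: str | Path) -> None:
    """Export a trial fixture's payload as a trial-table CSV."""
    if fixture.kind != "trial":
        raise InvalidInputError(f"fixture {fixture.name!r} is not a trial fixture")
    fixture.payload.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_fixture_csv(path: str | Path) -> Trial:
    from .trial_sim import trials_from_frame

    trials = trials_from_frame(pd.read_csv(path))
    if len(trials) != 1:
        raise InvalidInputError("fixture CSV must contain exactly one trial")
    return trials[0]
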