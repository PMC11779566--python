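"""Diagnostic-accuracy bookkeeping for the bias detectors.

Confusion-matrix accounting against the simulation ground truth, exact
(Clopper-Pearson) binomial confidence intervals for sensitivity and
specificity, the pooled two-proportion z comparison, and the Buderer
sample-size formula for diagnostic accuracy studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .detectors import BiasCall
from .errors import DegenerateEstimateError, InvalidInputError

__all__ = [
    "ConfusionMatrix",
    "ProportionCI",
    "confusion",
    "clopper_pearson",
    "two_proportion_z",
    "buderer_sample_size",
    "accuracy_report_frame",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of one detector's calls against the known truth.

    Positive = flagged as biased.  tp+fn = biased trials, fp+tn =
    unbiased trials.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)

    def sensitivity_ci(self, conf: float = 0.95) -> "ProportionCI":
        return clopper_pearson(self.tp, self.tp + self.fn, conf)

    def specificity_ci(self, conf: float = 0.95) -> "ProportionCI":
        return clopper_pearson(self.tn, self.fp + self.tn, conf)


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its exact (Clopper-Pearson) interval."""

    successes: int
    trials: int
    estimate: float
    conf_level: float
    low: float
    high: float


def confusion(calls: Sequence[BiasCall], truths: Sequence[str]) -> ConfusionMatrix:
    """Tally detector calls against truth labels ('biased'/'unbiased')."""
    if len(calls) != len(truths):
        raise InvalidInputError(
            f"{len(calls)} calls vs {len(truths)} truth labels"
        )
    tp = fp = fn = tn = 0
    for call, truth in zip(calls, truths):
        if truth not in ("biased", "unbiased"):
            raise InvalidInputError(f"unknown truth label {truth!r}")
        if truth == "biased":
            tp += call.flagged
            fn += not call.flagged
        else:
            fp += call.flagged
            tn += not call.flagged
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(successes: int, trials: int, conf: float = 0.95) -> ProportionCI:
    """Exact binomial interval via beta quantiles.

    Boundary conventions: successes = 0 gives low = 0 and
    successes = trials gives high = 1.
    """
    if trials < 1:
        raise InvalidInputError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise InvalidInputError("successes must lie in [0, trials]")
    low, high = proportion_confint(successes, trials, alpha=1 - conf, method="beta")
    low = 0.0 if successes == 0 else float(low)
    high = 1.0 if successes == trials else float(high)
    return ProportionCI(
        successes=successes,
        trials=trials,
        estimate=successes / trials,
        conf_level=conf,
        low=low,
        high=high,
    )


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z-test; returns (z, two-sided p).

    z = (p2 - p1) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (x1 + x2) / (n1 + n2).
    """
    if n1 < 1 or n2 < 1:
        raise InvalidInputError("sample sizes must be >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateEstimateError("pooled proportion is degenerate (0 or 1)")
    z, p = proportions_ztest([x2, x1], [n2, n1])
    return float(z), float(p)


def buderer_sample_size(
    expected_sens: float | None = None,
    prevalence: float = 0.5,
    precision: float = 0.10,
    conf: float = 0.95,
    expected_spec: float | None = None,
) -> int:
    """Required number of subjects (here: trials) for a diagnostic accuracy study.

    Buderer's formula: n = ceil(z^2 S (1-S) / (d^2 prev)) driven by the
    expected sensitivity S, or with denominator (1 - prev) when driven by
    specificity.  When both targets are given the larger n is returned.
    """
    for name, v in (("prevalence", prevalence), ("precision", precision), ("conf", conf)):
        if not 0 < v < 1:
            raise InvalidInputError(f"{name} must lie in (0, 1)")
    if expected_sens is None and expected_spec is None:
        raise InvalidInputError("at least one of expected_sens/expected_spec is required")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    sizes = []
    if expected_sens is not None:
        if not 0 < expected_sens < 1:
            raise InvalidInputError("expected_sens must lie in (0, 1)")
        sizes.append(z**2 * expected_sens * (1 - expected_sens) / (precision**2 * prevalence))
    if expected_spec is not None:
        if not 0 < expected_spec < 1:
            raise InvalidInputError("expected_spec must lie in (0, 1)")
        sizes.append(
            z**2 * expected_spec * (1 - expected_spec) / (precision**2 * (1 - prevalence))
        )
    return int(math.ceil(max(sizes)))


def accuracy_report_frame(matrices: dict[str, ConfusionMatrix], conf: float = 0.95) -> pd.DataFrame:
    """Per-method accuracy table (proportions on the 0-1 scale)."""
    rows = []
    for method, cm in matrices.items():
        se_ci = cm.sensitivity_ci(conf)
        sp_ci = cm.specificity_ci(conf)
        rows.append(
            {
                "method": method,
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                "sensitivity": cm.sensitivity,
                "sens_ci_low": se_ci.low, "sens_ci_high": se_ci.high,
                "specificity": cm.specificity,
                "spec_ci_low": sp_ci.low, "spec_ci_high": sp_ci.high,
            }
        )
    return pd.DataFrame(rows)
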