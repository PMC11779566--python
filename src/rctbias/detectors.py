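"""The two competing single-trial selection-bias detectors.

``significance_test``
    The conventional baseline-balance check: a two-sided z-test on the
    mean difference of the baseline covariate; p < alpha flags bias.
    A p-value of exactly alpha (equivalently, a confidence limit of
    exactly zero) is treated as non-significant, i.e. not flagged.

``i2_test``
    The trial-adjusted, simulated-comparator-trial (SCT) based I² test.
    For each configured SCT group size, two null comparator trials are
    built on the test trial's observed baseline range (their pairwise
    fixed-effect I² is 0%), the test trial's baseline mean difference is
    added as a third study, and the trial is flagged when the pooled I²
    exceeds 0%.

Two SCT constructions are available:

``"moment"`` (default)
    Each comparator arm carries the exact moments of the uniform
    distribution on the observed range [lo, hi]: mean (lo+hi)/2 and
    SD (hi-lo)/sqrt(12).  Both arms being identical, the pair's I² = 0%
    holds identically and the test is deterministic given the trial.

``"sampled"``
    Each comparator arm is a fresh uniform sample from [lo, hi],
    summarised; pairs are regenerated (accept/reject) until their
    two-study fixed-effect meta-analysis gives I² = 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationFailureError, InvalidConfigError, InvalidInputError
from .meta_engine import ArmSummary, EffectEstimate, fixed_effect_pool, mean_difference, summarize_arms
from .trial_sim import Trial

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "BiasCall",
    "SCTParams",
    "SCT",
    "significance_test",
    "significance_test_summaries",
    "derive_sct_params",
    "params_from_summaries",
    "moment_sct_pair",
    "generate_sct_pair",
    "i2_test",
    "i2_test_summaries",
]

DEFAULT_GROUP_SIZES: tuple[int, ...] = (100, 200, 400, 600)
_RULES = ("any", "all", "largest")


@dataclass(frozen=True)
class BiasCall:
    """Outcome of one detector on one trial: a flag plus its evidence."""

    method: str  # "significance_test" | "i2_test"
    flagged: bool
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SCTParams:
    """Trial-adjusted comparator settings: observed value range + group sizes."""

    value_low: float
    value_high: float
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES

    def __post_init__(self) -> None:
        if not self.value_low < self.value_high:
            raise InvalidConfigError(
                f"degenerate value range [{self.value_low}, {self.value_high}]"
            )
        if len(self.group_sizes) == 0 or any(g < 2 for g in self.group_sizes):
            raise InvalidConfigError("group_sizes must be nonempty with sizes >= 2")
        object.__setattr__(self, "group_sizes", tuple(int(g) for g in self.group_sizes))


@dataclass(frozen=True)
class SCT:
    """A simulated comparator trial: two arms of the baseline variable only."""

    arm_a: ArmSummary
    arm_b: ArmSummary

    def mean_difference(self, alpha: float = 0.05) -> EffectEstimate:
        return mean_difference(self.arm_a, self.arm_b, alpha)


# -- baseline significance test ---------------------------------------------

def significance_test_summaries(
    a: ArmSummary, b: ArmSummary, alpha: float = 0.05
) -> BiasCall:
    est = mean_difference(a, b, alpha)
    # Strict inequality implements the boundary convention: p = alpha
    # (one CI limit exactly zero) is non-significant.
    flagged = bool(est.p < alpha)
    return BiasCall(
        method="significance_test",
        flagged=flagged,
        detail={"md": est.point, "se": est.se, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "z": est.z, "p": est.p, "alpha": alpha},
    )


def significance_test(trial: Trial, alpha: float = 0.05) -> BiasCall:
    """Flag bias when the arms' baseline means differ at level ``alpha``."""
    a, b = summarize_arms(trial)
    return significance_test_summaries(a, b, alpha)


# -- SCT-based I² test -------------------------------------------------------

def derive_sct_params(
    trial: Trial, group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES
) -> SCTParams:
    """Comparator settings from the trial: min/max of its observed baselines."""
    lo = float(trial.baseline.min())
    hi = float(trial.baseline.max())
    return SCTParams(value_low=lo, value_high=hi, group_sizes=tuple(group_sizes))


def params_from_summaries(
    a: ArmSummary, b: ArmSummary, group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES
) -> SCTParams:
    """Moment-matched range when only arm summaries are available.

    A uniform distribution with the arms' pooled mean m and SD s spans
    m ± sqrt(3)·s; that interval stands in for the unobserved min/max.
    """
    m = (a.n * a.mean + b.n * b.mean) / (a.n + b.n)
    pooled_var = (
        (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    ) / max(a.n + b.n - 2, 1)
    half = np.sqrt(3.0 * pooled_var)
    if half <= 0:
        raise InvalidConfigError("zero variance: cannot derive a value range")
    return SCTParams(value_low=m - half, value_high=m + half, group_sizes=tuple(group_sizes))


def moment_sct_pair(params: SCTParams, group_size: int) -> tuple[SCT, SCT]:
    """Deterministic null comparator pair on the configured range.

    Both arms of both comparators carry the exact uniform moments of
    [value_low, value_high]; the pair's two-study I² is identically 0%.
    """
    mean = (params.value_low + params.value_high) / 2.0
    sd = (params.value_high - params.value_low) / np.sqrt(12.0)
    arm = ArmSummary(n=int(group_size), mean=float(mean), sd=float(sd))
    sct = SCT(arm_a=arm, arm_b=arm)
    return sct, sct


def generate_sct_pair(
    params: SCTParams,
    group_size: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[SCT, SCT, int]:
    """Sampled comparator pair, regenerated until its pooled I² is 0%.

    Returns ``(sct1, sct2, n_regenerations)`` where ``n_regenerations``
    counts rejected pairs (0 when the first draw is accepted).
    """

    def _draw() -> SCT:
        a = rng.uniform(params.value_low, params.value_high, size=group_size)
        b = rng.uniform(params.value_low, params.value_high, size=group_size)
        return SCT(
            arm_a=ArmSummary(n=group_size, mean=float(a.mean()), sd=float(a.std(ddof=1))),
            arm_b=ArmSummary(n=group_size, mean=float(b.mean()), sd=float(b.std(ddof=1))),
        )

    for attempt in range(max_attempts):
        s1, s2 = _draw(), _draw()
        pooled = fixed_effect_pool([s1.mean_difference(), s2.mean_difference()])
        if pooled.i2_percent == 0.0:
            return s1, s2, attempt
    raise GenerationFailureError(
        f"no comparator pair with 0% I2 within {max_attempts} attempts"
    )


def _sct_pair(params, size, rng, sct_mode, max_attempts):
    if sct_mode == "moment":
        s1, s2 = moment_sct_pair(params, size)
        return s1, s2, 0
    if sct_mode == "sampled":
        if rng is None:
            raise InvalidInputError("sct_mode='sampled' requires an rng")
        return generate_sct_pair(params, size, rng, max_attempts)
    raise InvalidConfigError(f"unknown sct_mode {sct_mode!r}")


def i2_test_summaries(
    a: ArmSummary,
    b: ArmSummary,
    params: SCTParams,
    rng: np.random.Generator | None = None,
    *,
    sct_mode: str = "moment",
    rule: str = "any",
    alpha: float = 0.05,
    max_attempts: int = 1000,
) -> BiasCall:
    """I² test on arm summaries, with comparator settings supplied explicitly."""
    if rule not in _RULES:
        raise InvalidConfigError(f"rule must be one of {_RULES}")
    trial_md = mean_difference(a, b, alpha)
    i2_by_size: dict[int, float] = {}
    regen: dict[int, int] = {}
    for size in params.group_sizes:
        s1, s2, n_regen = _sct_pair(params, size, rng, sct_mode, max_attempts)
        meta = fixed_effect_pool(
            [s1.mean_difference(alpha), s2.mean_difference(alpha), trial_md], alpha
        )
        i2_by_size[size] = meta.i2_percent
        regen[size] = n_regen
    positives = [i2 > 0.0 for i2 in i2_by_size.values()]
    if rule == "any":
        flagged = any(positives)
    elif rule == "all":
        flagged = all(positives)
    else:  # largest
        flagged = i2_by_size[max(params.group_sizes)] > 0.0
    return BiasCall(
        method="i2_test",
        flagged=bool(flagged),
        detail={
            "i2_by_size": i2_by_size,
            "md": trial_md.point,
            "se": trial_md.se,
            "sct_mode": sct_mode,
            "rule": rule,
            "regenerations": regen,
        },
    )


def i2_test(
    trial: Trial,
    params: SCTParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    sct_mode: str = "moment",
    rule: str = "any",
    alpha: float = 0.05,
    max_attempts: int = 1000,
) -> BiasCall:
    """SCT-based I² test on a trial; params default to the trial's own range."""
    if params is None:
        params = derive_sct_params(trial)
    a, b = summarize_arms(trial)
    return i2_test_summaries(
        a, b, params, rng, sct_mode=sct_mode, rule=rule, alpha=alpha, max_attempts=max_attempts
    )
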