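"""Effect estimation and fixed-effect meta-analysis.

Implements the statistical core shared by the outcome analysis and both
selection-bias detectors: mean difference (MD) and risk difference (RD)
with normal-approximation inference, and inverse-variance fixed-effect
pooling with Cochran's Q and the I² heterogeneity statistic,

    I² = max(0, (Q - df) / Q) * 100.

Inference is z-based throughout (no t correction, no continuity or
zero-cell corrections); degenerate estimates with zero standard error
raise :class:`~rctbias.errors.DegenerateEstimateError` rather than
producing p-values of 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateEstimateError, InvalidInputError
from .trial_sim import Trial

__all__ = [
    "ArmSummary",
    "EffectEstimate",
    "MetaResult",
    "summarize_arms",
    "mean_difference",
    "risk_difference",
    "fixed_effect_pool",
    "arm_summaries_to_frame",
    "arm_summaries_from_frame",
]


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics of one trial arm.

    ``mean``/``sd`` summarise the baseline covariate; ``failures`` counts
    outcome scores of 1 (treatment failure).
    """

    n: int
    mean: float
    sd: float
    failures: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("arm must contain at least one subject")
        if self.sd < 0:
            raise InvalidInputError("sd must be nonnegative")
        if not 0 <= self.failures <= self.n:
            raise InvalidInputError("failures must lie in [0, n]")

    @property
    def risk(self) -> float:
        return self.failures / self.n


@dataclass(frozen=True)
class EffectEstimate:
    measure: str  # "MD" | "RD"
    point: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    alpha: float = 0.05


@dataclass(frozen=True)
class MetaResult:
    pooled: EffectEstimate
    Q: float
    df: int
    i2_percent: float


def summarize_arms(trial: Trial) -> tuple[ArmSummary, ArmSummary]:
    """Per-arm (A, B) baseline mean, sample SD (n-1), n and failure count."""
    out = []
    for arm in ("A", "B"):
        values = trial.arm_baselines(arm)
        if values.size == 0:
            raise InvalidInputError(f"arm {arm} is empty")
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        out.append(
            ArmSummary(
                n=int(values.size),
                mean=float(values.mean()),
                sd=sd,
                failures=int(trial.arm_outcomes(arm).sum()),
            )
        )
    return out[0], out[1]


def _finish(measure: str, point: float, se: float, alpha: float) -> EffectEstimate:
    if se <= 0 or not np.isfinite(se):
        raise DegenerateEstimateError(f"{measure} standard error is zero; inference undefined")
    z = point / se
    crit = stats.norm.ppf(1 - alpha / 2)
    return EffectEstimate(
        measure=measure,
        point=point,
        se=se,
        ci_low=point - crit * se,
        ci_high=point + crit * se,
        z=z,
        p=float(2 * stats.norm.sf(abs(z))),
        alpha=alpha,
    )


def mean_difference(a: ArmSummary, b: ArmSummary, alpha: float = 0.05) -> EffectEstimate:
    """MD = mean_A - mean_B with SE = sqrt(sd_a^2/n_a + sd_b^2/n_b)."""
    se = float(np.sqrt(a.sd**2 / a.n + b.sd**2 / b.n))
    return _finish("MD", a.mean - b.mean, se, alpha)


def risk_difference(a: ArmSummary, b: ArmSummary, alpha: float = 0.05) -> EffectEstimate:
    """RD = risk_A - risk_B with the unpooled binomial standard error."""
    ra, rb = a.risk, b.risk
    se = float(np.sqrt(ra * (1 - ra) / a.n + rb * (1 - rb) / b.n))
    return _finish("RD", ra - rb, se, alpha)


def fixed_effect_pool(estimates: Sequence[EffectEstimate], alpha: float = 0.05) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Q, df and I².

    Weights are w_i = 1/se_i²; Q = Σ w_i (θ_i - θ̂)²; df = k - 1;
    I² = 100·(Q - df)/Q truncated below at 0 (so I² = 0 ⇔ Q ≤ df).
    """
    if len(estimates) < 2:
        raise InvalidInputError("pooling requires at least two estimates")
    measures = {e.measure for e in estimates}
    if len(measures) != 1:
        raise InvalidInputError(f"cannot pool mixed measures {sorted(measures)}")
    theta = np.array([e.point for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise InvalidInputError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled_point = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    Q = float(np.sum(w * (theta - pooled_point) ** 2))
    df = len(estimates) - 1
    i2 = 0.0 if Q <= df else 100.0 * (Q - df) / Q
    return MetaResult(
        pooled=_finish(measures.pop(), pooled_point, pooled_se, alpha),
        Q=Q,
        df=df,
        i2_percent=i2,
    )


# -- CSV interface for real trial summaries ---------------------------------

ARM_COLUMNS = ["trial_id", "arm", "n", "mean", "sd", "failures"]


def arm_summaries_to_frame(rows: dict[str, tuple[ArmSummary, ArmSummary]]) -> pd.DataFrame:
    records = []
    for tid, (a, b) in rows.items():
        for arm, s in zip("AB", (a, b)):
            records.append(
                {"trial_id": tid, "arm": arm, "n": s.n, "mean": s.mean, "sd": s.sd,
                 "failures": s.failures}
            )
    return pd.DataFrame(records, columns=ARM_COLUMNS)


def arm_summaries_from_frame(frame: pd.DataFrame) -> dict[str, tuple[ArmSummary, ArmSummary]]:
    """Read per-arm rows (columns trial_id, arm, n, mean, sd, failures)."""
    missing = set(ARM_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    out: dict[str, tuple[ArmSummary, ArmSummary]] = {}
    for tid, g in frame.groupby("trial_id", sort=False):
        by_arm = {}
        for _, row in g.iterrows():
            by_arm[str(row["arm"])] = ArmSummary(
                n=int(row["n"]), mean=float(row["mean"]), sd=float(row["sd"]),
                failures=int(row["failures"]),
            )
        if set(by_arm) != {"A", "B"}:
            raise InvalidInputError(f"trial {tid} must have exactly arms A and B")
        out[str(tid)] = (by_arm["A"], by_arm["B"])
    return out
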