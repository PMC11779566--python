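"""End-to-end orchestration of the simulation study.

``run_study`` simulates a full study, applies both detectors to every
trial, computes the per-trial outcome risk difference, tallies the
detectors' diagnostic accuracy against the simulation truth, compares
the two sensitivities with a pooled z-test, and derives the bias
severity curve (percent of biased trials per severity whose outcome RD
is significant in favour of arm A).  ``replicate_study`` repeats the
whole study over derived seeds to average the stochastic accuracy
measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import detectors, trial_sim
from .accuracy import ConfusionMatrix, accuracy_report_frame, confusion, two_proportion_z
from .errors import DegenerateEstimateError, InvalidInputError
from .meta_engine import risk_difference, summarize_arms
from .trial_sim import StudyConfig, Trial, trials_to_frame

__all__ = ["StudyReport", "run_study", "severity_curve", "replicate_study"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class StudyReport:
    """All study-level outputs: per-trial records, accuracy, severity curve."""

    config: StudyConfig
    per_trial: pd.DataFrame
    confusion: dict[str, ConfusionMatrix]
    accuracy: pd.DataFrame
    severity: pd.DataFrame
    z_sensitivity: float
    p_sensitivity: float


def _favour_a(rd_point: float, rd_p: float, alpha: float) -> bool:
    """'Significant in favour of A': fewer failures in A (RD < 0) at level alpha."""
    return rd_point < 0 and rd_p < alpha


def _analyse_trial(
    trial: Trial,
    rng: np.random.Generator,
    *,
    group_sizes: Sequence[int],
    sct_mode: str,
    rule: str,
    alpha: float,
) -> dict:
    a, b = summarize_arms(trial)
    sig = detectors.significance_test_summaries(a, b, alpha)
    params = detectors.derive_sct_params(trial, group_sizes)
    i2 = detectors.i2_test_summaries(
        a, b, params, rng, sct_mode=sct_mode, rule=rule, alpha=alpha
    )
    rd = risk_difference(a, b, alpha)
    rec = {
        "trial_id": trial.trial_id,
        "truth": trial.truth,
        "severity_k": -1 if trial.severity_k is None else trial.severity_k,
        "md": sig.detail["md"],
        "md_se": sig.detail["se"],
        "md_p": sig.detail["p"],
        "rd": rd.point,
        "rd_se": rd.se,
        "rd_ci_low": rd.ci_low,
        "rd_ci_high": rd.ci_high,
        "rd_p": rd.p,
        "rd_favour_a": _favour_a(rd.point, rd.p, alpha),
        "sig_flag": sig.flagged,
        "i2_flag": i2.flagged,
    }
    for size, value in i2.detail["i2_by_size"].items():
        rec[f"i2_at_{size}"] = value
    return rec


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    *,
    group_sizes: Sequence[int] = detectors.DEFAULT_GROUP_SIZES,
    sct_mode: str = "moment",
    rule: str = "any",
    alpha: float = 0.05,
    figures: bool = False,
) -> StudyReport:
    """Simulate, detect with both methods, and summarise accuracy.

    When ``out_dir`` is given, writes trials.csv, per_trial_results.csv,
    accuracy.csv and severity.csv (plus SVG figures when ``figures``);
    outputs are byte-reproducible for a fixed config.
    """
    trials = trial_sim.simulate_study(config)
    records = []
    for i, trial in enumerate(trials):
        det_rng = np.random.default_rng([config.seed, i, 101])
        records.append(
            _analyse_trial(
                trial, det_rng, group_sizes=group_sizes, sct_mode=sct_mode,
                rule=rule, alpha=alpha,
            )
        )
    per_trial = pd.DataFrame(records)

    truths = list(per_trial["truth"])
    matrices = {
        "significance_test": confusion(
            [detectors.BiasCall("significance_test", bool(f)) for f in per_trial["sig_flag"]],
            truths,
        ),
        "i2_test": confusion(
            [detectors.BiasCall("i2_test", bool(f)) for f in per_trial["i2_flag"]], truths
        ),
    }
    accuracy = accuracy_report_frame(matrices)
    try:
        z, p = two_proportion_z(
            matrices["significance_test"].tp,
            config.n_biased,
            matrices["i2_test"].tp,
            config.n_biased,
        )
    except DegenerateEstimateError:  # both detectors flagged none or all
        z, p = float("nan"), float("nan")
    report = StudyReport(
        config=config,
        per_trial=per_trial,
        confusion=matrices,
        accuracy=accuracy,
        severity=_severity_from_frame(per_trial),
        z_sensitivity=z,
        p_sensitivity=p,
    )
    if out_dir is not None:
        _write_outputs(report, trials, Path(out_dir), figures)
    return report


def _severity_from_frame(per_trial: pd.DataFrame) -> pd.DataFrame:
    biased = per_trial[per_trial["truth"] == "biased"]
    if biased.empty:
        raise InvalidInputError("study contains no biased trials")
    rows = []
    for k, g in biased.groupby("severity_k", sort=True):
        rows.append(
            {
                "severity_k": int(k),
                "n_trials": len(g),
                "t_percent": 100.0 * g["rd_favour_a"].mean(),
            }
        )
    return pd.DataFrame(rows)


def severity_curve(report: StudyReport) -> pd.DataFrame:
    """Per severity k: percent of biased trials with RD significant favouring A."""
    return _severity_from_frame(report.per_trial)


def _write_outputs(
    report: StudyReport, trials: list[Trial], out_dir: Path, figures: bool
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_to_frame(trials).to_csv(
        out_dir / "trials.csv", index=False, float_format=_FLOAT_FMT
    )
    report.per_trial.to_csv(
        out_dir / "per_trial_results.csv", index=False, float_format=_FLOAT_FMT
    )
    report.accuracy.to_csv(out_dir / "accuracy.csv", index=False, float_format=_FLOAT_FMT)
    report.severity.to_csv(out_dir / "severity.csv", index=False, float_format=_FLOAT_FMT)
    if figures:
        _write_figures(report, out_dir)


def _write_figures(report: StudyReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.per_trial.reset_index()
    fig, ax = plt.subplots(figsize=(7, 4))
    for truth, color in (("biased", "tab:red"), ("unbiased", "tab:blue")):
        sub = frame[frame["truth"] == truth]
        ax.errorbar(
            sub.index, sub["rd"],
            yerr=1.96 * sub["rd_se"], fmt="o", ms=3, color=color,
            label=truth, alpha=0.7, lw=0.8,
        )
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("trial")
    ax.set_ylabel("risk difference (A - B)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "rd_scatter.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(report.severity["severity_k"], report.severity["t_percent"], "o-")
    ax.set_xlabel("bias severity k (subverted allocations)")
    ax.set_ylabel("trials with RD significant favouring A (%)")
    ax.set_ylim(-2, 102)
    fig.tight_layout()
    fig.savefig(out_dir / "severity_curve.svg")
    plt.close(fig)


def replicate_study(
    config: StudyConfig,
    n_replicates: int,
    **run_kwargs,
) -> pd.DataFrame:
    """Re-run the whole study with derived seeds; one summary row per replicate.

    Replicate r uses seed ``[config.seed, r]`` folded into a fresh
    config, so replicates are independent and individually reproducible.
    """
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    rows = []
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2**31))
        rep_config = StudyConfig(**{**config.to_dict(), "seed": rep_seed})
        report = run_study(rep_config, **run_kwargs)
        cm_sig = report.confusion["significance_test"]
        cm_i2 = report.confusion["i2_test"]
        rows.append(
            {
                "replicate": r,
                "seed": rep_seed,
                "sens_sig": cm_sig.sensitivity,
                "sens_i2": cm_i2.sensitivity,
                "spec_sig": cm_sig.specificity,
                "spec_i2": cm_i2.specificity,
                "z_sensitivity": report.z_sensitivity,
            }
        )
    return pd.DataFrame(rows)
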