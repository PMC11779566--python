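"""Run the full simulation study and report detector accuracy.

100 trials (50 biased at severities k = 33..42, 50 unbiased), both
detectors applied to each, accuracy tallied against the known truth,
and the severity curve (percent of biased trials per k whose outcome
risk difference is significant in favour of arm A).
"""

from rctbias import StudyConfig, run_study, severity_curve

report = run_study(StudyConfig(seed=1))

print(report.accuracy.to_string(index=False))
print(f"\nsensitivity comparison (pooled z): z = {report.z_sensitivity:.1f}, "
      f"p = {report.p_sensitivity:.2g}")
print("\nseverity curve (T% = trials with RD significant favouring A):")
print(severity_curve(report).to_string(index=False))

# Sensitivity is TP/(TP+FN) over the 50 biased trials; specificity is
# TN/(FP+TN) over the 50 unbiased ones, each with an exact binomial CI.
# T% rises with k: the more allocations subverted, the more the outcome
# estimate is inflated in favour of arm A.
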