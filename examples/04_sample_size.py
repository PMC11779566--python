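"""Size a diagnostic-accuracy study with Buderer's formula.

How many trials must a simulation study contain to estimate a detector's
sensitivity and specificity to a given precision?
"""

from rctbias import buderer_sample_size

n = buderer_sample_size(
    expected_sens=0.85, prevalence=0.50, precision=0.10, conf=0.95
)
print(f"expected Se 85%, prevalence 50%, precision 10%, 95% confidence -> n = {n}")

n_worst = buderer_sample_size(expected_sens=0.50, prevalence=0.50)
print(f"worst-case Se 50% (maximum variance)                            -> n = {n_worst}")

# n = ceil(z^2 S(1-S) / (d^2 prev)): 98 trials at the first setting,
# which the study protocol rounds up to 100 (50 biased, 50 unbiased).
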