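"""Simulate one unbiased and one biased trial and inspect their arms.

Each trial has 100 subjects per arm, a uniform baseline covariate on
[1.00, 4.50] and a binary outcome (failure iff baseline > 2.00).  The
biased trial forces the 39 lowest baseline values into arm A, the way a
subverted allocation would.
"""

import numpy as np

from rctbias import (
    build_biased_trial,
    build_unbiased_trial,
    generate_allocation,
    generate_baseline_values,
    summarize_arms,
)

rng = np.random.default_rng(1)
allocation = generate_allocation(200, block_size=4, rng=rng)
values = generate_baseline_values(200, 1.00, 4.50, 2, rng)

for label, trial in [
    ("unbiased", build_unbiased_trial(allocation, values, rng)),
    ("biased k=39", build_biased_trial(allocation, values, 39, rng)),
]:
    a, b = summarize_arms(trial)
    print(f"{label:12s} arm A: mean {a.mean:.3f} (sd {a.sd:.3f}), {a.failures} failures")
    print(f"{'':12s} arm B: mean {b.mean:.3f} (sd {b.sd:.3f}), {b.failures} failures")

# The biased trial's arm A received the lowest baseline values, so its
# baseline mean and its failure count drop below arm B's: a spurious
# treatment benefit created purely by subverting the allocation.
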