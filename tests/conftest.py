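import numpy as np
import pytest

from rctbias import StudyConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_config():
    """A miniature but structurally complete study (fast end-to-end runs)."""
    return StudyConfig(
        n_per_arm=20,
        n_trials=10,
        n_biased=6,
        severity_values=(6, 8, 10),
        trials_per_severity=2,
        seed=7,
    )
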