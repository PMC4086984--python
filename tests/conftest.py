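import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kneepca import (
    SyntheticConfig,
    correct_subject,
    evaluate_subject,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The simulated healthy cohort: 20 subjects x 2 sides, per-side
    misalignment uniform in [8, 15] degrees, default noise."""
    return generate_cohort(SyntheticConfig())


@pytest.fixture(scope="session")
def corrected_cohort(default_cohort):
    """(subject, truth, correction, metrics) for the default cohort."""
    out = []
    for subject, truth in default_cohort:
        result = correct_subject(subject)
        metrics = evaluate_subject(subject, result, truth=truth.deformity)
        out.append((subject, truth, result, metrics))
    return out


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Same cohort design without stride-to-stride noise (fewer cycles:
    noise-free cycles are identical)."""
    cfg = SyntheticConfig(noise_sd=0.0, n_cycles=3)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
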