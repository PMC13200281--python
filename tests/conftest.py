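import logging

import numpy as np
import pytest

from rnfltrend.synthetic import CohortDesign, generate_cohort

# sampler warnings about flagged diagnostics are expected in short test runs
logging.getLogger("rnfltrend.sampler").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 8-eye global-sector cohort, clean (no rounding, no outliers)."""
    design = CohortDesign(n_eyes=8, round_cirrus=False)
    cohort, truth = generate_cohort(design, seed=42)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
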