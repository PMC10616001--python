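"""Shared fixtures: small synthetic template, cohort and derived pattern.

Unit tests run on a 32x32x24 grid at 4 mm spacing (same physical extent as
the full-resolution analyses) with a reduced cohort, which keeps the whole
suite fast while exercising identical code paths.
"""

import numpy as np
import pytest

from covpet import ssm, synthetic


@pytest.fixture(scope="session")
def template():
    return synthetic.make_template((32, 32, 24), (4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def planted_pattern(template):
    return synthetic.make_planted_pattern(
        template, synthetic.default_pattern_spec(template)
    )


@pytest.fixture(scope="session")
def cohort(template, planted_pattern):
    cfg = synthetic.CohortConfig(n_control=14, n_patient=18, seed=11)
    return synthetic.simulate_cohort(template, planted_pattern, cfg)


@pytest.fixture(scope="session")
def derived(cohort):
    """(pattern, raw, z) from the small fixture cohort."""
    return ssm.derive(cohort.scans, cohort.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
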