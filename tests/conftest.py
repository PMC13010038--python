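import numpy as np
import pytest

from dataclasses import replace

import oxiburden as ox


@pytest.fixture(scope="session")
def default_cohort():
    """The calibrated desk-scale study cohort (shared across tests)."""
    spec = ox.default_calibration()
    traces, truth = ox.generate_cohort(spec)
    return spec, traces, truth


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    _, traces, truth = default_cohort
    pairs = [ox.apply_quality_rules(tr) for tr in traces]
    return [p[0] for p in pairs], [p[1] for p in pairs], truth


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, artifact-light cohort for functional tests."""
    spec = replace(
        ox.default_calibration(),
        n_neonates=4,
        seed=424242,
        duration_median_d=0.5,
        duration_min_d=0.2,
        duration_max_d=0.8,
    )
    return spec, *ox.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
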