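"""Shared fixtures: default parameters, headline profile, cached sweeps.

Expensive computations (the full factorial sweep, the 20-seed sensitivity
ensemble) are session-scoped so every test sees the same objects without
re-running the model.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dermalkin import (
    BACProfile,
    GridSpec,
    default_parameters,
    grid_sweep,
    run_sensitivity,
    simulate,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def headline_profile():
    """The reference single-run profile: 1 h absorption to 0.06 g/dL."""
    return BACProfile.triangular(1.0, 0.06, 0.018)


@pytest.fixture(scope="session")
def headline_result(headline_profile, params):
    return simulate(headline_profile, params)


@pytest.fixture(scope="session")
def grid_table(params):
    """Metrics for the full 8x5 factorial design at average parameters."""
    return grid_sweep(GridSpec(), params)


@pytest.fixture(scope="session")
def sensitivity_ensemble():
    """Twenty independent-seed LHS analyses of the 1 h / 0.05 g/dL profile."""
    profile = BACProfile.triangular(1.0, 0.05, 0.018)
    return [run_sensitivity(profile, n=50, seed=s) for s in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
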