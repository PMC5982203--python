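"""Shared fixtures.

The two desk-scale reference experiments train real models and take a few
minutes each, so they run once per session and are shared between the
acceptance tests and the directional property tests.
"""

import pytest


@pytest.fixture(scope="session")
def penalty_experiment():
    """Hard-preset penalty study: primary model vs. penalty-retrained model."""
    from psep.experiments import penalty_benchmark

    return penalty_benchmark(seed=1)


@pytest.fixture(scope="session")
def count_experiment():
    """Easy-preset count recovery across the full density range."""
    from psep.experiments import count_recovery_benchmark

    return count_recovery_benchmark(seed=1)
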