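import numpy as np
import pytest

from sympnet.synthetic import (
    CohortConfig,
    GroupConfig,
    default_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    """Four small groups — fast cohort for structural pipeline tests."""
    groups = [
        GroupConfig(
            label=f"[{2 * k}-{2 * k + 1}]",
            n=120,
            target_delta=2.0 * k + 0.5,
            baseline_total=13.0 + k,
            strength_baseline=2.2 - 0.3 * k,
            strength_change=2.4 - 0.2 * k,
            strength_postchange=2.4 - 0.2 * k,
        )
        for k in range(4)
    ]
    return CohortConfig(groups=groups, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The default eight-group study-condition cohort (seed 42)."""
    return generate_cohort(default_config())
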