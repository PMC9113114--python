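from dataclasses import replace

import numpy as np
import pytest

from cerebmotor.simulate import CohortConfig, generate_cohort, generate_volume_table


def cohort_config(n_asd: int, n_td: int, seed: int = 0) -> CohortConfig:
    base = CohortConfig()
    return CohortConfig(
        asd=replace(base.asd, n=n_asd), td=replace(base.td, n=n_td), seed=seed
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 24+24 cohort reused by model-fitting tests."""
    return generate_cohort(cohort_config(24, 24, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """10,000 + 10,000 cohort for law-of-large-numbers calibration checks."""
    return generate_cohort(cohort_config(10_000, 10_000, seed=12))


@pytest.fixture(scope="session")
def small_volumes(small_cohort):
    return generate_volume_table(small_cohort, seed=13)
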