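import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hlseason as h

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table2_counts() -> np.ndarray:
    """Packaged monthly diagnosis counts of the 41,405-case cohort."""
    return h.seer_hl_monthly_counts()


@pytest.fixture(scope="session")
def small_cohort() -> list[h.CaseRecord]:
    """Seeded 2,000-case synthetic cohort with a little missingness."""
    config = h.SimConfig(
        n_cases=2000,
        seed=7,
        p_flagged=0.01,
        p_missing_month=0.005,
        p_missing_age=0.002,
        p_missing_stage=0.05,
    )
    return h.simulate_registry(config)


@pytest.fixture(scope="session")
def clean_cohort(small_cohort) -> list[h.CaseRecord]:
    cohort, _report = h.apply_exclusions(
        small_cohort,
        ["dco-autopsy-only", "unknown-month", "missing-age", "missing-stage"],
    )
    h.assign_strata(cohort, h.StratumScheme())
    return cohort
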