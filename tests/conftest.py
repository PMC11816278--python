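import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nfpmarkov as nm
from nfpmarkov.simulate import recovery_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def toy_frame():
    """Six participants: two below age 30, one with a single screen."""
    rows = []

    def add(pid, age, n_screens, smoking="low", betel="none"):
        for r in range(1, n_screens + 1):
            rows.append(
                dict(
                    id=pid, round=r, age=age, sex="male", education="low",
                    living_area="urban", screening_place="small",
                    opmd="negative", smoking_state=smoking, betel_state=betel,
                )
            )

    add("A", 29, 3)          # excluded: age

    add("B", 25, 2)          # excluded: age
    add("C", 45, 1)          # excluded: single screen
    add("D", 30, 2)          # retained (age boundary)
    add("E", 60, 3, smoking="high", betel="low")
    add("F", 75, 2, smoking="none", betel="high")
    return pd.DataFrame(rows)


@pytest.fixture
def toy_panel():
    return nm.PanelDataset(toy_frame(), provenance="toy")


@pytest.fixture(scope="session")
def cohort_20k():
    """Mixed-covariate cohort under the default study conditions."""
    cfg = nm.default_config(n_participants=20_000, seed=7)
    return nm.generate_population(cfg)


@pytest.fixture(scope="session")
def cohort_50k():
    """The standard fixture for MCMC validation."""
    cfg = nm.default_config(n_participants=50_000, seed=42)
    return nm.generate_population(cfg)


@pytest.fixture(scope="session")
def mcmc_50k(cohort_50k):
    return nm.fit_mcmc(
        cohort_50k, "smoking", ["male", "opmd_positive"], seed=42
    )


@pytest.fixture(scope="session")
def ml_50k(cohort_50k):
    return nm.fit_ml(cohort_50k, "smoking", ["male", "opmd_positive"])


def low_dose_cohort(behavior: str, seed: int, n: int = 200_000):
    """Two-screen cohort starting in the low-dose state at reference
    covariates, evolving under the default true dynamics."""
    return nm.generate_population(recovery_config(behavior, "low", seed=seed, n_participants=n))
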