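import numpy as np
import pandas as pd
import pytest

from qgmix.cohort import DemographicParams, generate_covariates
from qgmix.landscape import sample_exposure_matrix
from qgmix.pipeline import covariates_for_fit


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 2,000-subject cohort at default marginals (no outcome)."""
    return generate_covariates(DemographicParams(n=2000), seed=12345)


@pytest.fixture(scope="session")
def small_exposures(small_cohort) -> pd.DataFrame:
    """Matching 17-column exposure matrix from the direct sampler."""
    return sample_exposure_matrix(len(small_cohort), seed=54321)


@pytest.fixture(scope="session")
def small_covariates(small_cohort) -> pd.DataFrame:
    return covariates_for_fit(small_cohort)


def planted_dataset(
    n: int, seed: int, preset: str = "per_component", include_income: bool = False
):
    """Cohort + exposures + outcome generated from a planted preset,
    with the intercept calibrated to the reference prevalence."""
    from qgmix.pipeline import RunConfig, simulate_cohort

    cfg = RunConfig(
        seed=seed,
        demographics=DemographicParams(n=n),
        preset=preset,
        bootstrap=0,
        include_income=include_income,
        exposure_mode="direct",
    )
    cohort, exposures, coeffs = simulate_cohort(cfg)
    return cohort, exposures, coeffs
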