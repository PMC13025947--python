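import pytest

from ngri.centile import fit_centile_model
from ngri.synthetic import default_trend, gen_model_cohort


@pytest.fixture(scope="session")
def female_cohort_20k():
    """Training-scale synthetic female red-cell cohort with ground truth."""
    ages, values, truth = gen_model_cohort(20000, "female", seed=7)
    return ages, values, truth


@pytest.fixture(scope="session")
def fitted_female_20k(female_cohort_20k):
    ages, values, _ = female_cohort_20k
    return fit_centile_model(ages, values, analyte="RBC", sex="female")


@pytest.fixture(scope="session")
def male_cohort_20k():
    ages, values, truth = gen_model_cohort(20000, "male", seed=8)
    return ages, values, truth


@pytest.fixture(scope="session")
def female_trend():
    return default_trend("female")
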