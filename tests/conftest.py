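import pytest

from vetelicit import default_cohort_config, fit_cohort, generate_cohort


@pytest.fixture(scope="session")
def cohort24():
    """The stated-world synthetic cohort: 24 experts in 5 practices."""
    return generate_cohort(default_cohort_config(seed=7))


@pytest.fixture(scope="session")
def fitted24(cohort24):
    """Beta priors fitted to the noiseless synthetic cohort."""
    return fit_cohort(cohort24)
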