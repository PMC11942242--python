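import pytest

from rhabdosignal.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 5000-report synthetic cohort with default planted structure."""
    config = CohortConfig(n_reports=5000, seed=42)
    reports, truth = generate_cohort(config)
    return config, reports, truth


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    from rhabdosignal.faers_io import deduplicate

    config, reports, truth = small_cohort
    return config, deduplicate(reports), truth
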