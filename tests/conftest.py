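import pytest

from tampgx.simulate import (
    ASIAN_LIKE_ALLELE_FREQUENCIES,
    CohortConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def asian_config():
    return CohortConfig(
        mode="hardy_weinberg",
        allele_frequencies=dict(ASIAN_LIKE_ALLELE_FREQUENCIES),
        ethnicity="asian_like",
    )


@pytest.fixture(scope="session")
def cohort900(default_config):
    """One default-condition cohort at the study scale."""
    return generate_cohort(default_config, seed=42)
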