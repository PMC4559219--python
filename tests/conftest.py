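import pytest

from diabsurv import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort with some late-onset diabetics, shared
    read-only across tests."""
    cfg = CohortConfig(n_persons=4000, seed=11)
    return generate_cohort(cfg, onset_year_distribution={2008: 0.05, 2009: 0.05})


@pytest.fixture(scope="session")
def perfect_coding_config():
    """Study conditions under which ascertainment should be error-free:
    every diabetic coded E11 in every enrolled quarter, no drug-only
    cases, no E10/E13 mislabelling."""
    return CohortConfig(
        n_persons=8000,
        years=(2007, 2008),
        coding_completeness=1.0,
        drug_treatment_fraction=0.0,
        dropout_rate=0.0,
        code_mix={"e11": 1.0, "e14": 0.0, "both": 0.0, "e10": 0.0, "e13": 0.0},
        seed=7,
    )
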