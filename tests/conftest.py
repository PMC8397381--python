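import pandas as pd
import pytest

from tcrad import GeneratorConfig, generate_cohort, load_cutoffs


@pytest.fixture(scope="session")
def table1():
    """The bundled published cutoff table."""
    return load_cutoffs("table1_fixture")


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_participants=300, seed=7))


@pytest.fixture()
def tiny_roster():
    return pd.DataFrame(
        {
            "participant_id": ["a", "b", "c"],
            "sex": ["male", "female", "male"],
            "age": [14, 15, 16],
            "area": ["urban", "rural", "urban"],
            "school_type": ["public", "public", "private"],
            "ses_points": [20, 50, 90],
        }
    )
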