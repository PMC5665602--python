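from pathlib import Path

import pytest

from edscores import default_cohort_spec, generate

EXAMPLE_CSV = Path(__file__).resolve().parent.parent / "examples" / "cohort_example.csv"


@pytest.fixture(scope="session")
def default_cohort():
    """The default 114-patient synthetic cohort (100 survivors / 14 non-survivors)."""
    return generate(default_cohort_spec(seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """A 10x scaled synthetic cohort for the stochastic-direction checks."""
    return generate(default_cohort_spec(seed=0, scale=10))
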