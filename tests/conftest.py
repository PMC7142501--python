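import pandas as pd
import pytest

import herbenergy as he


@pytest.fixture(scope="session")
def ref_summary():
    return he.reference_summary()


@pytest.fixture(scope="session")
def mean_rec(ref_summary):
    """One-row frame with every variable at its study-scale mean."""
    return he.mean_record(ref_summary)


@pytest.fixture(scope="session")
def default_data():
    """One default synthetic trial dataset (11 trials x 6 sheep)."""
    return he.generate_dataset(he.GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def default_data_with_balance():
    return he.generate_dataset(he.GeneratorConfig(seed=202), return_balance=True)
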