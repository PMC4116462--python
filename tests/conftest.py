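import numpy as np
import pandas as pd
import pytest

from flymet import synth
from flymet.validation import qc_toy_fixture


@pytest.fixture(scope="session")
def small_design():
    return synth.DesignSpec(columns={"AE": 120, "C18": 140})


@pytest.fixture(scope="session")
def small_table(small_design):
    """Small two-column table with default planted effects."""
    effects = synth.EffectSpec(seed=321)
    return synth.generate_table(small_design, effects)


@pytest.fixture()
def qc_fixture():
    return qc_toy_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def balanced_metadata(n_lines=5, ages=(3, 10, 24), reps=2) -> pd.DataFrame:
    spec = synth.DesignSpec(
        n_lines=n_lines, ages=ages, replicates_per_cell=reps,
        columns={"AE": 1},
    )
    return synth.generate_design(spec)
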