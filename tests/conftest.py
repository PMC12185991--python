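import numpy as np
import pandas as pd
import pytest

from dysbiome import AbundanceTable, SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """4 samples x 3 species, percent scale."""
    data = pd.DataFrame(
        {
            "k__Bacteria|p__P1|c__C1|o__O1|f__F1|g__Bacteroides|s__Bacteroides_a": [10.0, 20.0, 5.0, 1.0],
            "k__Bacteria|p__P1|c__C1|o__O1|f__F1|g__Bacteroides|s__Bacteroides_b": [30.0, 10.0, 15.0, 2.0],
            "k__Bacteria|p__P2|c__C2|o__O2|f__F2|g__Prevotella|s__Prevotella_c": [60.0, 70.0, 80.0, 97.0],
        },
        index=["S1", "S2", "S3", "S4"],
    )
    return AbundanceTable(data=data, rank="species")


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort, shared across read-only tests."""
    return generate_cohort(SimConfig(seed=7))
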