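import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from concord.signatures import Condition, DifferentialTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(ids, lfc, p, adj=None, agent="HNK", timepoint=24.0, modality="gene"):
    df = pd.DataFrame({"analyte_id": ids, "log2fc": lfc, "p_value": p})
    if adj is not None:
        df["adj_p"] = adj
    return DifferentialTable(Condition(agent, timepoint, modality), df)


@pytest.fixture
def small_table():
    return make_table(
        ["GRN", "BDNF", "NTRK2", "FLAT"],
        [2.0, -3.0, 1.5, 0.0],
        [0.005, 0.02, 0.005, 0.5],
        adj=[0.02, 0.08, 0.02, 0.9],
    )
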