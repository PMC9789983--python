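import numpy as np
import pandas as pd
import pytest

from symptombn import reference_network, sample_binary
from symptombn.graph import CPT, DAG, DiscreteBayesianNetwork


@pytest.fixture(scope="session")
def ref_net():
    return reference_network()


@pytest.fixture(scope="session")
def ref_sample_2k(ref_net):
    """A small ancestral sample used by several structure/evaluation tests."""
    return sample_binary(ref_net, 2000, seed=11)


@pytest.fixture()
def two_node_net():
    """fatigue -> anxiety with the reference marginal and conditionals."""
    dag = DAG(("fatigue", "anxiety"), [("fatigue", "anxiety")])
    cpts = {
        "fatigue": CPT("fatigue", (), [0.647]),
        "anxiety": CPT("anxiety", ("fatigue",), [0.086, 0.331]),  # index 0 = absent parent
    }
    return DiscreteBayesianNetwork(dag, cpts)


def make_binary_frame(counts: dict[tuple[int, ...], int], columns) -> pd.DataFrame:
    """Build a binary DataFrame with exact row-pattern counts."""
    rows = []
    for pattern, n in counts.items():
        rows.extend([list(pattern)] * n)
    return pd.DataFrame(np.array(rows, dtype=np.int8), columns=list(columns))
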