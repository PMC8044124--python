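import numpy as np
import pandas as pd
import pytest

from coresist import SensitivityCalls, SimulationConfig, generate_bundle


def make_calls(table, drugs=None):
    """Build SensitivityCalls from a dict {cell_line: [call, ...]} with
    'R'/'S'/None shorthand."""
    mapping = {"R": "resistant", "S": "sensitive", None: np.nan}
    lines = list(table)
    n_drugs = len(next(iter(table.values())))
    drugs = drugs or [f"d{j + 1}" for j in range(n_drugs)]
    frame = pd.DataFrame(
        [[mapping[c] for c in row] for row in table.values()],
        index=lines,
        columns=drugs,
        dtype=object,
    )
    return SensitivityCalls(calls=frame)


@pytest.fixture
def toy_calls():
    # 5 lines × 2 drugs: (R,R),(R,S),(S,R),(R,missing),(R,R)
    return make_calls(
        {
            "c1": ["R", "R"],
            "c2": ["R", "S"],
            "c3": ["S", "R"],
            "c4": ["R", None],
            "c5": ["R", "R"],
        }
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cell_lines=150,
        n_drugs=20,
        n_genes=300,
        n_racs_amp=25,
        n_racs_del=25,
        n_icpg=25,
        emt_set_size=60,
        csc_set_size=120,
        n_lineages=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)
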