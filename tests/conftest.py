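import numpy as np
import pandas as pd
import pytest

from comparetx import (
    CellLinePanel,
    DrugResponseMatrix,
    ExpressionMatrix,
    SimulationConfig,
)


def make_response(values, line_ids=None, compound_ids=None, panel_labels=None):
    """Build a DrugResponseMatrix from a plain array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    line_ids = line_ids or [f"L{i + 1}" for i in range(n)]
    compound_ids = compound_ids or [f"D{j + 1}" for j in range(m)]
    panel = None
    if panel_labels is not None:
        panel = CellLinePanel(pd.Series(list(panel_labels), index=line_ids))
    return DrugResponseMatrix(
        pd.DataFrame(values, index=line_ids, columns=compound_ids), panel
    )


def make_expression(values, probe_ids=None, line_ids=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    probe_ids = probe_ids or [f"P{i + 1}" for i in range(p)]
    line_ids = line_ids or [f"L{j + 1}" for j in range(n)]
    return ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=line_ids))


from comparetx.validation import null_simulation_config as null_config  # noqa: F401


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_dataset():
    """A modest simulated screen shared by fast integration tests."""
    from comparetx import simulate_dataset

    config = SimulationConfig(seed=7, n_background_genes=200)
    response, expression, truth = simulate_dataset(config)
    return config, response, expression, truth
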