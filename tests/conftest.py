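import numpy as np
import pandas as pd
import pytest

from sebic.expression import CtTable, ExpressionMatrix, ReplicatedExpression


@pytest.fixture
def ct_table() -> CtTable:
    """Two genes, control plus one treatment, one replicate each."""
    records = pd.DataFrame(
        [
            ("g1", "undiff", "r1", 28.0, 18.0),
            ("g1", "F", "r1", 25.0, 18.0),
            ("g2", "undiff", "r1", 22.0, 15.0),
            ("g2", "F", "r1", 20.0, 15.0),
        ],
        columns=["gene", "condition", "replicate", "ct_target", "ct_housekeeping"],
    )
    return CtTable(records, control_condition="undiff")


@pytest.fixture
def small_replicates() -> ReplicatedExpression:
    """2 genes x 2 conditions with 2-3 replicates per cell (one missing)."""
    values = np.full((2, 2, 3), np.nan)
    values[0, 0] = [2.0, 4.0, np.nan]
    values[0, 1] = [1.0, 2.0, 3.0]
    values[1, 0] = [5.5, np.nan, np.nan]
    values[1, 1] = [8.0, 8.0, 8.0]
    return ReplicatedExpression(("g1", "g2"), ("c1", "c2"), values)


@pytest.fixture
def simple_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(6)),
        tuple(f"c{j}" for j in range(8)),
        rng.normal(size=(6, 8)),
    )
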