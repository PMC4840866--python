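import numpy as np
import pandas as pd
import pytest

from temptrans.core_io import ExpressionMatrix
from temptrans.simdata import default_design


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def toy_matrix(design):
    """4 genes x 15 libraries; replicates within a condition identical."""
    rng = np.random.default_rng(7)
    conds = ["T25", "T4", "T0", "TM4", "T44"]
    means = pd.DataFrame(
        rng.uniform(1, 100, size=(4, 5)),
        index=[f"g{i}" for i in range(4)],
        columns=conds,
    )
    cols = {}
    for lib in design.index:
        cols[lib] = means[design.loc[lib, "condition"]]
    return ExpressionMatrix(pd.DataFrame(cols), design)
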