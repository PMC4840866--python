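"""Shared test utilities."""

import pandas as pd

from temptrans.core_io import ExpressionMatrix
from temptrans.simdata import default_design


def matrix_from_means(means: pd.DataFrame, n_reps: int = 3) -> ExpressionMatrix:
    """Expand a genes x conditions mean table into identical replicates."""
    design = default_design(tuple(means.columns), n_reps)
    cols = {lib: means[design.loc[lib, "condition"]] for lib in design.index}
    return ExpressionMatrix(pd.DataFrame(cols), design, tuple(means.columns))
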