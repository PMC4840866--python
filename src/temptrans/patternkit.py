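"""Temperature-course U/D/M expression-pattern classification.

Adjacent conditions along the cold course (25 -> 4 -> 0 -> -4 degC by
default) are compared with the higher temperature as denominator:
FC = (mean at lower temperature + c) / (mean at higher temperature + c).
Each step gets a letter: U (up, FC >= 2), D (down, FC <= 0.5) or
M (maintain, 0.5 < FC < 2), giving 3^(k-1) possible patterns over a
k-condition course — 27 for the default four-point course.

By default the letters depend on fold change only; an optional
significance gate re-labels steps failing the differential-probability
criterion as M, for analyses that only trust significant steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import COLD_COURSE, ExpressionMatrix

__all__ = [
    "PatternCall",
    "classify_step",
    "classify_pattern",
    "all_patterns",
    "pattern_census",
    "classify_matrix",
]


def classify_step(
    mean_lower_temp: float,
    mean_higher_temp: float,
    pseudocount: float = 1.0,
) -> tuple[str, float]:
    """Letter and fold change for one temperature-decrease step.

    FC = (lower + c) / (higher + c), the higher temperature being the
    denominator.  U iff FC >= 2, D iff FC <= 0.5, M otherwise.
    """
    fc = (mean_lower_temp + pseudocount) / (mean_higher_temp + pseudocount)
    if fc >= 2.0:
        return "U", fc
    if fc <= 0.5:
        return "D", fc
    return "M", fc


@dataclass
class PatternCall:
    gene_id: str
    letters: str
    step_fcs: tuple[float, ...]


def classify_pattern(
    gene_id: str,
    course_means: Sequence[float],
    pseudocount: float = 1.0,
) -> PatternCall:
    """Classify a gene's ordered course means into its U/D/M pattern.

    ``course_means`` runs from the warmest to the coldest condition;
    each adjacent pair yields one letter.
    """
    if len(course_means) < 2:
        raise ValueError("course must have >= 2 conditions")
    letters = []
    fcs = []
    for higher, lower in zip(course_means, course_means[1:]):
        letter, fc = classify_step(lower, higher, pseudocount)
        letters.append(letter)
        fcs.append(fc)
    return PatternCall(gene_id, "".join(letters), tuple(fcs))


def all_patterns(n_steps: int = 3) -> list[str]:
    """All 3^n_steps letter patterns in lexicographic D < M < U order."""
    return ["".join(p) for p in product("DMU", repeat=n_steps)]


def classify_matrix(
    matrix: ExpressionMatrix,
    course: Sequence[str] = COLD_COURSE,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene pattern calls over a condition course.

    Returns a frame with ``gene_id``, ``pattern`` and one ``fc_step<i>``
    column per step.  Raises if a course condition is absent from the
    design.
    """
    missing = [c for c in course if c not in matrix.condition_order]
    if missing:
        raise ValueError(f"course conditions missing from design: {missing}")
    means = matrix.condition_means()[list(course)]
    rows = []
    for gene, m in means.iterrows():
        call = classify_pattern(gene, m.to_list(), pseudocount)
        row = {"gene_id": gene, "pattern": call.letters}
        for i, fc in enumerate(call.step_fcs, start=1):
            row[f"fc_step{i}"] = fc
        rows.append(row)
    return pd.DataFrame(rows)


def pattern_census(
    matrix: ExpressionMatrix,
    course: Sequence[str] = COLD_COURSE,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Gene counts per pattern class, zeros included.

    Always returns exactly 3^(k-1) classes for a k-condition course;
    the counts sum to the number of genes.
    """
    calls = classify_matrix(matrix, course, pseudocount)
    keys = all_patterns(len(course) - 1)
    counts = pd.Series(0, index=keys, dtype=int)
    if len(calls):
        observed = calls["pattern"].value_counts()
        counts.loc[observed.index] = observed
    return counts
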