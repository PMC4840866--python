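"""Differential-expression calling and treatment-overlap analysis.

Differential expression follows the noise-dominance scheme popularised
by nonparametric tools for replicate-poor RNA-seq: the within-condition
replicate scatter defines an empirical noise cloud of (|M|, D) pairs
(M = log2 fold change with pseudocount, D = absolute FPKM difference),
and a gene's differential probability q is the fraction of noise pairs
strictly dominated by its treatment-vs-control signal.  A gene is
called up when FC >= 2 and q > 0.8, down when FC <= 0.5 and q > 0.8
(fold change on pseudocounted condition-mean FPKM).

Also here: exact set algebra over per-treatment DEG sets (overlap /
specificity reports) and temperature-specific expressed transcript
(SET) detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "NoiseDistribution",
    "OverlapReport",
    "noise_distribution",
    "deg_probability",
    "fold_change_direction",
    "call_degs",
    "overlap_analysis",
    "specific_expressed",
]


@dataclass
class NoiseDistribution:
    """Pooled within-condition replicate (|M|, D) noise pairs."""

    abs_m: np.ndarray
    d: np.ndarray

    def __len__(self) -> int:
        return len(self.abs_m)


def noise_distribution(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> NoiseDistribution:
    """Pool (|M|, D) over every ordered replicate pair and every gene.

    For replicate libraries a, b within a condition and each gene,
    M = log2((a + c) / (b + c)) and D = |a - b| on FPKM.  Every ordered
    pair contributes, so each unordered pair appears twice (with equal
    |M| and D).  Conditions with fewer than two replicates contribute
    nothing; at least one contributing condition is required.
    """
    abs_m: list[np.ndarray] = []
    d: list[np.ndarray] = []
    c = pseudocount
    for cond in matrix.condition_order:
        libs = matrix.libraries_for(cond)
        if len(libs) < 2:
            continue
        for la, lb in permutations(libs, 2):
            a = matrix.values[la].to_numpy(dtype=float)
            b = matrix.values[lb].to_numpy(dtype=float)
            abs_m.append(np.abs(np.log2((a + c) / (b + c))))
            d.append(np.abs(a - b))
    if not abs_m:
        raise ValueError("no condition has >= 2 replicates")
    return NoiseDistribution(np.concatenate(abs_m), np.concatenate(d))


def deg_probability(abs_m_signal: float, d_signal: float,
                    noise: NoiseDistribution) -> float:
    """Fraction of noise pairs strictly dominated by the signal pair.

    q = P(|M_noise| < |M_signal| and D_noise < D_signal), estimated on
    the pooled noise cloud.  Monotone non-decreasing in both signal
    coordinates.
    """
    if len(noise) == 0:
        raise ValueError("empty noise distribution")
    dominated = (noise.abs_m < abs_m_signal) & (noise.d < d_signal)
    return float(np.mean(dominated))


def fold_change_direction(
    treatment_mean: float,
    control_mean: float,
    pseudocount: float = 1.0,
    fc_threshold: float = 2.0,
) -> tuple[float, str]:
    """Pseudocounted fold change and its up/down/none classification.

    FC = (treatment + c) / (control + c); up iff FC >= fc_threshold,
    down iff FC <= 1 / fc_threshold (both inclusive), else none.
    """
    fc = (treatment_mean + pseudocount) / (control_mean + pseudocount)
    if fc >= fc_threshold:
        return fc, "up"
    if fc <= 1.0 / fc_threshold:
        return fc, "down"
    return fc, "none"


def call_degs(
    matrix: ExpressionMatrix,
    control_condition: str = "T25",
    fc_threshold: float = 2.0,
    q_threshold: float = 0.8,
    pseudocount: float = 1.0,
    q_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call DEGs for every treatment condition against the control.

    Returns a tidy frame with one row per (gene, comparison):
    ``gene_id, comparison, treatment, fc, log2fc, q, direction``.
    direction is "up" iff FC >= fc_threshold and q > q_threshold,
    "down" iff FC <= 1/fc_threshold and q > q_threshold, else "none".

    ``q_values`` (genes x treatment-condition columns) substitutes
    externally computed differential probabilities for the built-in
    noise-dominance q.
    """
    if control_condition not in matrix.condition_order:
        raise ValueError(f"control condition {control_condition!r} not in design")
    treatments = [c for c in matrix.condition_order if c != control_condition]
    means = matrix.condition_means()
    noise = None
    if q_values is None:
        noise = noise_distribution(matrix, pseudocount)
    c = pseudocount
    rows = []
    ctrl = means[control_condition].to_numpy(dtype=float)
    for treat in treatments:
        tr = means[treat].to_numpy(dtype=float)
        fc = (tr + c) / (ctrl + c)
        log2fc = np.log2(fc)
        d = np.abs(tr - ctrl)
        for i, gene in enumerate(means.index):
            if q_values is not None:
                q = float(q_values.loc[gene, treat])
            else:
                q = deg_probability(abs(log2fc[i]), d[i], noise)
            if fc[i] >= fc_threshold and q > q_threshold:
                direction = "up"
            elif fc[i] <= 1.0 / fc_threshold and q > q_threshold:
                direction = "down"
            else:
                direction = "none"
            rows.append({
                "gene_id": gene,
                "comparison": f"{treat}_vs_{control_condition}",
                "treatment": treat,
                "fc": float(fc[i]),
                "log2fc": float(log2fc[i]),
                "q": q,
                "direction": direction,
            })
    return pd.DataFrame(rows)


def consistent_direction_calls(
    mean_table: pd.DataFrame,
    control: str,
    treatments: Sequence[str],
    pseudocount: float = 1.0,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene direction across several treatment-vs-control comparisons.

    ``mean_table`` holds condition-mean FPKM with one column per
    condition.  Each treatment gets an up/down/none label via
    :func:`fold_change_direction`; ``consistent`` is "up" or "down"
    when every treatment agrees on that label, otherwise "none".
    """
    rows = []
    for gene, r in mean_table.iterrows():
        dirs = {}
        for t in treatments:
            _, d = fold_change_direction(
                float(r[t]), float(r[control]), pseudocount, fc_threshold
            )
            dirs[t] = d
        uniq = set(dirs.values())
        consistent = uniq.pop() if len(uniq) == 1 and uniq != {"none"} else "none"
        rows.append({"gene_id": gene, **{f"dir_{t}": d for t, d in dirs.items()},
                     "consistent": consistent})
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class OverlapReport:
    """Exact set algebra over per-treatment DEG sets."""

    totals: dict[str, int]
    specific: dict[str, int]
    shared_all: set[str]
    region_sizes: dict[frozenset, int]

    def pairwise(self, a: str, b: str) -> int:
        """Size of the pairwise intersection of two treatment sets."""
        return sum(n for members, n in self.region_sizes.items()
                   if a in members and b in members)


def overlap_analysis(deg_sets: Mapping[str, Iterable[str]]) -> OverlapReport:
    """Venn-region accounting over per-treatment DEG sets.

    ``region_sizes`` maps every non-empty treatment combination
    (frozenset of treatment labels) to the number of genes belonging to
    exactly that combination; all 2^k - 1 regions are present as keys.
    """
    sets = {t: set(g) for t, g in deg_sets.items()}
    if len(sets) < 2:
        raise ValueError("need >= 2 treatment sets")
    names = list(sets)
    regions: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = 0
    universe = set().union(*sets.values())
    for gene in universe:
        members = frozenset(t for t in names if gene in sets[t])
        regions[members] += 1
    totals = {t: len(sets[t]) for t in names}
    specific = {t: regions[frozenset([t])] for t in names}
    shared_all = set.intersection(*sets.values()) if sets else set()
    return OverlapReport(totals, specific, shared_all, regions)


def specific_expressed(
    matrix: ExpressionMatrix, expressed_threshold: float = 0.0
) -> pd.DataFrame:
    """Temperature-specific expressed transcripts (SETs).

    A gene is condition-specific when its mean FPKM exceeds the
    detection threshold in exactly one condition.  Returns a frame with
    ``gene_id`` and ``condition`` columns (possibly empty).
    """
    means = matrix.condition_means()
    expressed = means > expressed_threshold
    n_cond = expressed.sum(axis=1)
    hits = expressed[n_cond == 1]
    rows = [
        {"gene_id": gene, "condition": row.index[row][0]}
        for gene, row in hits.iterrows()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "condition"])
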