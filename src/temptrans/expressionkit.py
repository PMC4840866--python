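"""Expression-level utilities.

FPKM computation, the high/medium/low expression categories, replicate
concordance (Pearson correlation on log2 FPKM), cumulative gene
detection as libraries accumulate, per-class expression summaries, and
qRT-PCR relative quantitation by the 2^-ddCt method.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "fpkm",
    "categorize",
    "replicate_pcc",
    "cumulative_detection",
    "class_expression_summary",
    "relative_expression",
]


def fpkm(
    fragment_counts: pd.DataFrame,
    effective_length_bp: pd.Series,
    total_mapped_fragments: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = 1e9 * C / (N * L) with C the fragment count for the gene in
    a library, L the transcript length in bp and N the library's total
    mapped fragments (defaults to each column's sum).
    """
    lengths = effective_length_bp.reindex(fragment_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for genes {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    if total_mapped_fragments is None:
        total_mapped_fragments = fragment_counts.sum(axis=0)
    totals = pd.Series(total_mapped_fragments).reindex(fragment_counts.columns)
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")
    out = fragment_counts.div(totals, axis=1).div(lengths, axis=0) * 1e9
    return out


def categorize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Label every (gene, library) cell high / medium / low.

    high iff FPKM > 50; medium iff 5 < FPKM <= 50; low iff FPKM <= 5.
    """
    vals = matrix.values
    out = pd.DataFrame("low", index=vals.index, columns=vals.columns)
    out = out.mask(vals > 5, "medium")
    out = out.mask(vals > 50, "high")
    return out


def replicate_pcc(
    matrix: ExpressionMatrix,
    log: bool = True,
    offset: float = 1.0,
) -> pd.DataFrame:
    """Library x library Pearson correlation of (log2-transformed) FPKM.

    Correlations are computed on log2(FPKM + offset) by default; pass
    ``log=False`` for raw values.  A zero-variance library yields NaN
    against every partner (undefined, not zero); the diagonal is 1
    where defined.
    """
    if len(matrix.genes) < 3:
        raise ValueError("need >= 3 genes for replicate correlation")
    x = matrix.values.to_numpy(dtype=float)
    if log:
        x = np.log2(x + offset)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=matrix.libraries, columns=matrix.libraries)


def cumulative_detection(
    matrix: ExpressionMatrix, detect_threshold: float = 0.0
) -> pd.Series:
    """Cumulative count of genes detected in at least one library so far.

    Libraries are walked in design (column) order; a gene is detected
    once its FPKM exceeds ``detect_threshold`` in any library seen.
    The result is non-decreasing and its final value is independent of
    the library order.
    """
    detected = matrix.values > detect_threshold
    cum = detected.cummax(axis=1).sum(axis=0)
    return cum.astype(int)


def class_expression_summary(
    matrix: ExpressionMatrix,
    class_map: Mapping[str, str],
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Average / maximum / median expression per transcript class.

    Each gene is first reduced to a single expression value across all
    libraries (``aggregate``: "mean" or "max"); the summary statistics
    are then taken per class.  Classes with no genes in the matrix are
    omitted.
    """
    if aggregate == "mean":
        per_gene = matrix.values.mean(axis=1)
    elif aggregate == "max":
        per_gene = matrix.values.max(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    rows = {}
    classes = pd.Series(class_map)
    for cls in classes.unique():
        genes = classes.index[classes == cls]
        vals = per_gene.reindex(genes).dropna()
        if vals.empty:
            continue
        rows[cls] = {
            "average": float(vals.mean()),
            "maximum": float(vals.max()),
            "median": float(vals.median()),
            "n_genes": int(len(vals)),
        }
    return pd.DataFrame(rows).T


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qRT-PCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_sample
         - (Ct_target - Ct_reference)_calibrator.
    """
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    if not np.isfinite(ddct):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-ddct))
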