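"""Bundled worked-example tables from a temperature-stress experiment.

Two small panels from a five-temperature (25, 4, 0, -4, 44 degC)
RNA-seq experiment in non-heading Chinese cabbage ship with the
package as concrete worked inputs:

* :func:`stress_deg_panel` — condition-mean FPKM for ten genes
  responsive in every treatment, with their reported regulation
  direction and functional annotation;
* :func:`cold_tf_panel` — log2 ratios and differential probabilities
  (q) of cold-responsive transcription-factor transcripts across the
  three cold-vs-control comparisons.

Both load as plain DataFrames for use in examples and analyses of the
differential-expression criterion.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["stress_deg_panel", "cold_tf_panel", "TREATMENTS", "CONTROL"]

CONTROL = "T25"
TREATMENTS = ("T4", "T0", "TM4", "T44")
COLD_TREATMENTS = ("T4", "T0", "TM4")


def _load(name: str) -> pd.DataFrame:
    with resources.files("temptrans.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def stress_deg_panel() -> pd.DataFrame:
    """Ten all-treatment-responsive genes: condition-mean FPKM + direction."""
    return _load("nhcc_stress_degs.tsv").set_index("gene_id")


def cold_tf_panel() -> pd.DataFrame:
    """Cold-responsive TF transcripts: per-comparison log2 ratio and q."""
    return _load("nhcc_cold_tfs.tsv").set_index("gene_id")
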