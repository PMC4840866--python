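"""Readers, writers and containers for the formats shared by every stage.

Three containers run through the whole pipeline:

* :class:`TranscriptSet` — assembled transcript (unigene) nucleotide
  sequences keyed by id.
* :class:`HitTable` — tabular BLAST evidence against protein or
  noncoding-RNA databases, in the classic 12-column dialect.
* :class:`ExpressionMatrix` — genes x libraries FPKM with a design that
  maps each library to an ordered temperature condition and replicate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TranscriptSet",
    "HitTable",
    "ExpressionMatrix",
    "DEFAULT_CONDITION_ORDER",
    "COLD_COURSE",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "filter_hits",
    "read_expression",
    "write_expression",
]

#: Default ordered temperature conditions: control, the three cold
#: treatments in decreasing temperature, then the heat treatment.
DEFAULT_CONDITION_ORDER: tuple[str, ...] = ("T25", "T4", "T0", "TM4", "T44")

#: The cold temperature-decrease course used for U/D/M pattern calling.
COLD_COURSE: tuple[str, ...] = ("T25", "T4", "T0", "TM4")

_NUC_RE = re.compile(r"^[ACGTNRYSWKMBDHV]+$")

#: Canonical 12-column tabular BLAST header (outfmt 6).
BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


@dataclass
class TranscriptSet:
    """Ordered mapping of transcript id to uppercase nucleotide sequence."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, seq in self.records.items():
            if not tid:
                raise ValueError("transcript id must be non-empty")
            if not seq:
                raise ValueError(f"empty sequence for transcript {tid!r}")
            seq = seq.upper()
            if not _NUC_RE.match(seq):
                raise ValueError(f"non-nucleotide characters in transcript {tid!r}")
            self.records[tid] = seq

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, tid: str) -> bool:
        return tid in self.records

    def __getitem__(self, tid: str) -> str:
        return self.records[tid]

    def ids(self) -> list[str]:
        return list(self.records)

    def items(self):
        return self.records.items()

    def lengths(self) -> dict[str, int]:
        return {tid: len(seq) for tid, seq in self.records.items()}


class HitTable:
    """BLAST tabular hits with a database label attached to every row.

    Thin wrapper around a :class:`pandas.DataFrame` with the 12 classic
    columns plus ``db_label``.
    """

    COLUMNS = BLAST_COLUMNS + ("db_label",)

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=list(self.COLUMNS))
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
        frame = frame[list(self.COLUMNS)].reset_index(drop=True)
        if len(frame):
            pid = frame["percent_identity"].astype(float)
            if ((pid < 0) | (pid > 100)).any():
                raise ValueError("percent_identity outside [0, 100]")
            if (frame["evalue"].astype(float) < 0).any():
                raise ValueError("negative evalue")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def queries(self) -> set[str]:
        return set(self.frame["query_id"])

    def for_query(self, query_id: str) -> pd.DataFrame:
        return self.frame[self.frame["query_id"] == query_id]

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping]) -> "HitTable":
        frame = pd.DataFrame(list(rows))
        if frame.empty:
            return cls()
        defaults = {
            "alignment_length": 0,
            "mismatches": 0,
            "gap_opens": 0,
            "q_start": 1,
            "q_end": 1,
            "s_start": 1,
            "s_end": 1,
            "bitscore": 0.0,
        }
        for col, val in defaults.items():
            if col not in frame.columns:
                frame[col] = val
        return cls(frame)

    def concat(self, other: "HitTable") -> "HitTable":
        return HitTable(pd.concat([self.frame, other.frame], ignore_index=True))

    def write(self, path: str | Path) -> None:
        """Write as 12-column tabular plus a trailing db_label column."""
        self.frame.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ExpressionMatrix:
    """Genes x libraries FPKM with the library -> condition design.

    ``values`` is indexed by gene id with one column per library;
    ``design`` is indexed by library id with ``condition`` and
    ``replicate`` columns.  ``condition_order`` fixes the temperature
    course ordering used downstream.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    condition_order: tuple[str, ...] = DEFAULT_CONDITION_ORDER

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative FPKM value in expression matrix")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"libraries missing from design: {sorted(missing)}")
        conds = set(self.design.loc[list(self.values.columns), "condition"])
        order = [c for c in self.condition_order if c in conds]
        extra = conds - set(order)
        if extra:
            raise ValueError(
                f"conditions {sorted(extra)} absent from condition_order"
            )
        self.condition_order = tuple(order)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)

    def libraries_for(self, condition: str) -> list[str]:
        mask = self.design["condition"] == condition
        return [l for l in self.design.index[mask] if l in self.values.columns]

    def condition_means(self) -> pd.DataFrame:
        """Arithmetic mean FPKM per condition, columns in course order."""
        cols = {c: self.values[self.libraries_for(c)].mean(axis=1)
                for c in self.condition_order}
        return pd.DataFrame(cols)

    def subset_conditions(self, conditions: Sequence[str]) -> "ExpressionMatrix":
        libs = [l for c in conditions for l in self.libraries_for(c)]
        return ExpressionMatrix(
            self.values[libs].copy(), self.design.loc[libs].copy(),
            tuple(conditions),
        )


def read_fasta(path: str | Path) -> TranscriptSet:
    """Read a FASTA file into a :class:`TranscriptSet`.

    Sequences are uppercased; record order is preserved.  Duplicate ids
    and empty sequences are hard errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate id {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id}")
        records[rec.id] = seq
    return TranscriptSet(records)


def write_fasta(transcripts: TranscriptSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tid, seq in transcripts.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_blast_tab(path: str | Path, db_label: str) -> HitTable:
    """Read 12-column tabular BLAST output, attaching ``db_label``.

    Extra trailing columns are tolerated and ignored.  Non-numeric
    numeric fields raise with the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                row = {
                    "query_id": parts[0],
                    "subject_id": parts[1],
                    "percent_identity": float(parts[2]),
                    "alignment_length": int(parts[3]),
                    "mismatches": int(parts[4]),
                    "gap_opens": int(parts[5]),
                    "q_start": int(parts[6]),
                    "q_end": int(parts[7]),
                    "s_start": int(parts[8]),
                    "s_end": int(parts[9]),
                    "evalue": float(parts[10]),
                    "bitscore": float(parts[11]),
                }
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            row["db_label"] = db_label
            rows.append(row)
    if not rows:
        return HitTable()
    return HitTable(pd.DataFrame(rows))


def filter_hits(hits: HitTable, max_evalue: float, min_identity: float) -> HitTable:
    """Keep rows with ``evalue < max_evalue`` and ``identity > min_identity``.

    Both comparisons are strict, matching the convention of thresholds
    quoted as "E-value < x, identity > y%".  Idempotent; tightening
    either threshold can only remove rows.
    """
    if not np.isfinite(max_evalue) or not np.isfinite(min_identity):
        raise ValueError("thresholds must be finite")
    f = hits.frame
    if f.empty:
        return HitTable()
    keep = (f["evalue"].astype(float) < max_evalue) & (
        f["percent_identity"].astype(float) > min_identity
    )
    return HitTable(f[keep])


def read_expression(
    path: str | Path,
    design_path: str | Path,
    condition_order: Sequence[str] = DEFAULT_CONDITION_ORDER,
) -> ExpressionMatrix:
    """Read an FPKM TSV (first column gene id) plus a design TSV.

    The design file has columns ``library_id``, ``condition``,
    ``replicate``.  Every matrix library must appear in the design;
    negative FPKM is a hard error.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    required = {"library_id", "condition", "replicate"}
    if not required <= set(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    design = design.set_index("library_id")
    return ExpressionMatrix(values, design, tuple(condition_order))


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     design_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if design_path is not None:
        matrix.design.to_csv(design_path, sep="\t", index_label="library_id")
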