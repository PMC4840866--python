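"""lncRNA identification cascade for de novo transcriptomes.

Candidate long noncoding RNAs are carved out of an assembled transcript
set by a fixed filter cascade:

1. drop transcripts with any protein-database hit (annotated coding);
2. drop transcripts shorter than 200 nt;
3. keep only transcripts called noncoding by BOTH coding-potential
   channels (a CNCI-style intrinsic scorer with decision boundary at 0
   and a CPC-style evidence-aware scorer with boundary at -1);
4. drop transcripts whose longest six-frame ORF exceeds 100 aa;
5. triage survivors on structural/known noncoding-RNA hits into
   pri-miRNA, other structural ncRNA, known lncRNA (known-lncRNA
   database hit) and novel lncRNA.

Every transcript receives exactly one final class plus a stage-by-stage
trace, and the cascade reports telescoping per-stage survivor counts.

The two built-in coding-potential scorers are transparent, deterministic
stand-ins calibrated to the published decision boundaries (negative =
noncoding; below -1 = noncoding); externally computed score tables can
be supplied instead for fidelity with the original tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .core_io import HitTable, TranscriptSet, filter_hits

__all__ = [
    "LncrnaVerdict",
    "CascadeParams",
    "CascadeReport",
    "longest_orf",
    "orf_coverage",
    "fickett_position_bias",
    "cnci_like_score",
    "cpc_like_score",
    "run_cascade",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = set("ACGT")

FINAL_CLASSES = (
    "annotated_coding",
    "too_short",
    "coding_potential",
    "orf_coding",
    "pri_miRNA",
    "other_ncRNA",
    "lncRNA_known",
    "lncRNA_novel",
)


def _frame_longest_orf(seq: str, offset: int) -> int:
    """Longest ATG..stop ORF (aa, stop excluded) in one reading frame.

    Codons containing ambiguity characters (N etc.) invalidate any open
    ORF they fall inside: an ORF must consist of unambiguous codons and
    terminate at an in-frame stop.
    """
    best = 0
    open_len = -1  # codons since ATG, -1 = no open ORF
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if not _BASES >= set(codon):
            open_len = -1
            continue
        if codon in _STOPS:
            if open_len > 0:
                best = max(best, open_len)
            open_len = -1
        elif open_len >= 0:
            open_len += 1
        elif codon == "ATG":
            open_len = 1
    return best


def longest_orf(sequence: str) -> int:
    """Length in amino acids of the longest ORF over all six frames.

    An ORF is ATG-initiated and must end at an in-frame stop codon
    within the transcript; the stop is not counted.  ORFs running off
    the end are ignored.  Returns 0 when no ORF exists.
    """
    seq = sequence.upper()
    rc = str(Seq(seq).reverse_complement())
    return max(
        _frame_longest_orf(s, f) for s in (seq, rc) for f in (0, 1, 2)
    )


def orf_coverage(sequence: str) -> float:
    """Fraction of the transcript covered by the longest ORF (stop included)."""
    aa = longest_orf(sequence)
    if aa == 0:
        return 0.0
    return min(1.0, (3 * aa + 3) / len(sequence))


def fickett_position_bias(sequence: str) -> float:
    """Fickett-style codon-position bias statistic in [0, 1].

    For each base the counts at the three codon positions are compared;
    strong periodicity (typical of coding sequence) pushes the statistic
    toward 1, uniform usage toward 0.  This is the position component of
    the classic testcode statistic, normalised rather than looked up in
    the original empirical tables.
    """
    seq = sequence.upper()
    biases = []
    for base in "ACGT":
        counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                counts[i % 3] += 1
        biases.append(max(counts) / (min(counts) + 1.0))
    # each bias >= ~1 for uniform usage; squash the average excess to [0, 1]
    mean_excess = sum(b - 1.0 for b in biases) / 4.0
    return mean_excess / (mean_excess + 1.0)


@dataclass(frozen=True)
class CascadeParams:
    """Thresholds of the filter cascade, defaults as published-style."""

    min_length: int = 200
    max_orf_aa: int = 100
    protein_max_evalue: float = 1e-5
    ncrna_max_evalue: float = 1e-5
    ncrna_min_identity: float = 90.0
    cnci_threshold: float = 0.0    # score below => noncoding
    cpc_threshold: float = -1.0    # score below => noncoding


def cnci_like_score(sequence: str) -> float:
    """Intrinsic coding-potential score; negative means noncoding.

    A monotone combination of longest-ORF coverage and the codon
    position-bias statistic, affinely placed so transcripts whose
    longest ORF spans most of their length score positive and
    transcripts with only short ORFs score negative.
    """
    cov = orf_coverage(sequence)
    bias = fickett_position_bias(sequence)
    return 2.0 * (cov - 0.65) + 0.2 * (bias - 0.5)


def cpc_like_score(sequence: str, protein_hits: HitTable | None = None,
                   max_evalue: float = 1e-5) -> float:
    """Evidence-aware coding-potential score; below -1 means noncoding.

    ORF coverage dominates; any qualifying protein-database hit is hard
    evidence of coding ability and clamps the score to >= 0.
    """
    import math

    aa = longest_orf(sequence)
    cov = orf_coverage(sequence)
    raw = 10.0 * (cov - 0.65) + 0.3 * math.tanh(aa / 100.0 - 1.0)
    if protein_hits is not None and len(protein_hits):
        good = protein_hits.frame["evalue"].astype(float) < max_evalue
        if good.any():
            return max(raw, 0.0)
    return raw


@dataclass
class LncrnaVerdict:
    """Per-transcript outcome of the cascade with its decision trace."""

    transcript_id: str
    final_class: str
    trace: list[tuple[str, str, str]] = field(default_factory=list)
    cnci_like: float | None = None
    cpc_like: float | None = None
    longest_orf_aa: int | None = None


@dataclass
class CascadeReport:
    """Telescoping per-stage survivor counts plus the final class census."""

    n_input: int
    stage_survivors: dict[str, int]
    class_counts: dict[str, int]


STAGES = ("annotation", "length", "coding_potential", "orf", "triage")


def _is_mirna_hit(row) -> bool:
    if row["db_label"] == "mirbase":
        return True
    return row["db_label"] == "rfam" and "mir" in str(row["subject_id"]).lower()


def run_cascade(
    transcripts: TranscriptSet,
    protein_hits: HitTable,
    ncrna_hits: HitTable,
    params: CascadeParams = CascadeParams(),
    cnci_scores: Mapping[str, float] | None = None,
    cpc_scores: Mapping[str, float] | None = None,
) -> tuple[list[LncrnaVerdict], CascadeReport]:
    """Run the five-stage lncRNA filter cascade over a transcript set.

    ``cnci_scores`` / ``cpc_scores`` substitute externally computed
    coding-potential tables for the built-in scorers.  Hits referencing
    transcripts absent from the set are ignored.

    Returns one verdict per input transcript (input order preserved)
    and a report with telescoping survivor counts.
    """
    known_ids = set(transcripts.ids())
    prot_by_query: dict[str, list] = {}
    for _, row in protein_hits.frame.iterrows():
        if row["query_id"] in known_ids:
            prot_by_query.setdefault(row["query_id"], []).append(row)
    nc_filtered = filter_hits(
        ncrna_hits, params.ncrna_max_evalue, params.ncrna_min_identity
    )
    nc_by_query: dict[str, list] = {}
    for _, row in nc_filtered.frame.iterrows():
        if row["query_id"] in known_ids:
            nc_by_query.setdefault(row["query_id"], []).append(row)

    verdicts: list[LncrnaVerdict] = []
    survivors = dict.fromkeys(STAGES, 0)

    for tid, seq in transcripts.items():
        v = LncrnaVerdict(transcript_id=tid, final_class="", trace=[])

        # stage 1: protein-database annotation
        prot = [r for r in prot_by_query.get(tid, [])
                if float(r["evalue"]) < params.protein_max_evalue]
        if prot:
            best = min(prot, key=lambda r: float(r["evalue"]))
            v.trace.append(("annotation", "removed",
                            f"{best['db_label']}:{best['subject_id']} "
                            f"E={float(best['evalue']):g}"))
            v.final_class = "annotated_coding"
            verdicts.append(v)
            continue
        v.trace.append(("annotation", "passed", "no protein hit"))
        survivors["annotation"] += 1

        # stage 2: length
        if len(seq) < params.min_length:
            v.trace.append(("length", "removed", f"{len(seq)} nt"))
            v.final_class = "too_short"
            verdicts.append(v)
            continue
        v.trace.append(("length", "passed", f"{len(seq)} nt"))
        survivors["length"] += 1

        # stage 3: dual coding-potential filter (conjunctive)
        if cnci_scores is not None:
            if tid not in cnci_scores:
                raise KeyError(
                    f"external intrinsic score table missing transcript {tid!r}")
            cnci = cnci_scores[tid]
        else:
            cnci = cnci_like_score(seq)
        if cpc_scores is not None:
            if tid not in cpc_scores:
                raise KeyError(
                    f"external evidence score table missing transcript {tid!r}")
            cpc = cpc_scores[tid]
        else:
            prot_table = HitTable.from_rows(
                [dict(r) for r in prot_by_query.get(tid, [])]
            )
            cpc = cpc_like_score(seq, prot_table, params.protein_max_evalue)
        v.cnci_like, v.cpc_like = float(cnci), float(cpc)
        noncoding = cnci < params.cnci_threshold and cpc < params.cpc_threshold
        if not noncoding:
            v.trace.append(("coding_potential", "removed",
                            f"cnci={cnci:.3f} cpc={cpc:.3f}"))
            v.final_class = "coding_potential"
            verdicts.append(v)
            continue
        v.trace.append(("coding_potential", "passed",
                        f"cnci={cnci:.3f} cpc={cpc:.3f}"))
        survivors["coding_potential"] += 1

        # stage 4: ORF size
        aa = longest_orf(seq)
        v.longest_orf_aa = aa
        if aa > params.max_orf_aa:
            v.trace.append(("orf", "removed", f"{aa} aa"))
            v.final_class = "orf_coding"
            verdicts.append(v)
            continue
        v.trace.append(("orf", "passed", f"{aa} aa"))
        survivors["orf"] += 1

        # stage 5: noncoding-database triage
        nc = nc_by_query.get(tid, [])
        mirna = [r for r in nc if _is_mirna_hit(r)]
        rfam_other = [r for r in nc
                      if r["db_label"] == "rfam" and not _is_mirna_hit(r)]
        noncode = [r for r in nc if r["db_label"] == "noncode"]
        if mirna:
            v.final_class = "pri_miRNA"
            ev = mirna[0]
        elif rfam_other:
            v.final_class = "other_ncRNA"
            ev = rfam_other[0]
        elif noncode:
            v.final_class = "lncRNA_known"
            ev = noncode[0]
        else:
            v.final_class = "lncRNA_novel"
            ev = None
        detail = ("no qualifying ncRNA hit" if ev is None
                  else f"{ev['db_label']}:{ev['subject_id']}")
        v.trace.append(("triage", v.final_class, detail))
        survivors["triage"] += 1
        verdicts.append(v)

    counts = dict.fromkeys(FINAL_CLASSES, 0)
    for v in verdicts:
        counts[v.final_class] += 1
    report = CascadeReport(
        n_input=len(transcripts),
        stage_survivors=survivors,
        class_counts=counts,
    )
    return verdicts, report
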