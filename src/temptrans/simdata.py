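"""Synthetic transcriptome data with planted, recoverable truth.

Three generators emulate the data shapes of a replicated temperature-
course RNA-seq study of a de novo assembled transcriptome:

* :func:`simulate_transcripts` — a mixed coding / noncoding transcript
  set in which every class sits clearly on one side of each downstream
  filter boundary (length 200 nt, ORF 100 aa, coding-potential scores);
* :func:`simulate_hits` — BLAST-style evidence tables (protein
  databases, miRNA families, structural ncRNA families, known-lncRNA
  database) consistent with the transcript classes;
* :func:`simulate_expression` — replicated FPKM matrices with planted
  differential expression at chosen fold changes, planted U/D/M
  temperature-course patterns, planted lncRNA-target correlation
  structure, and multiplicative log-normal replicate noise.

All generators are deterministic under a fixed integer seed; each
derives its own stream by pairing the seed with a fixed component tag,
so the three can be driven from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_CONDITION_ORDER,
    ExpressionMatrix,
    HitTable,
    TranscriptSet,
)
from .lncrnakit import longest_orf

__all__ = [
    "SimTruth",
    "default_design",
    "simulate_transcripts",
    "simulate_hits",
    "simulate_expression",
]

TRANSCRIPT_CLASSES = ("coding", "lncRNA", "pri_miRNA", "other_ncRNA", "short_nc")

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    ``transcript_class`` maps transcript id to its class;
    ``known_lncrna`` lists lncRNAs given a known-lncRNA database hit;
    ``de_status`` maps gene id -> condition -> (direction, planted FC);
    ``patterns`` maps gene id to its planted course pattern;
    ``coexpr_pairs`` lists (source, target, sign) planted correlations;
    ``decoys`` lists genes guaranteed uncorrelated with every source.
    """

    transcript_class: dict[str, str] = field(default_factory=dict)
    known_lncrna: set[str] = field(default_factory=set)
    de_status: dict[str, dict[str, tuple[str, float]]] = field(default_factory=dict)
    patterns: dict[str, str] = field(default_factory=dict)
    coexpr_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)

    def expected_verdict(self, transcript_id: str) -> str:
        """Final cascade class the planted truth implies."""
        cls = self.transcript_class[transcript_id]
        return {
            "coding": "annotated_coding",
            "short_nc": "too_short",
            "pri_miRNA": "pri_miRNA",
            "other_ncRNA": "other_ncRNA",
            "lncRNA": ("lncRNA_known" if transcript_id in self.known_lncrna
                       else "lncRNA_novel"),
        }[cls]


def default_design(
    conditions: Sequence[str] = DEFAULT_CONDITION_ORDER, n_replicates: int = 3
) -> pd.DataFrame:
    """Library design: ``n_replicates`` libraries per condition.

    The default emulates the 15-library layout of a five-temperature
    experiment with three biological replicates each.
    """
    rows = [
        {"library_id": f"{cond}_R{r}", "condition": cond, "replicate": r}
        for cond in conditions for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("library_id")


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), tag])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop, non-ATG codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon in _STOPS or codon == "ATG":
            continue
        out.append(codon)
    return "".join(out)


def _coding_sequence(rng: np.random.Generator, min_aa: int = 110,
                     max_aa: int = 250) -> str:
    """Transcript with one long planted ORF spanning most of its length.

    The ORF (ATG + non-stop codons + stop) covers 85-95 % of the
    transcript so the intrinsic coding-potential scorer sits clearly on
    the coding side of its boundary.
    """
    aa = int(rng.integers(min_aa, max_aa + 1))
    orf = "ATG" + _random_codons(rng, aa - 1) + str(rng.choice(_STOPS))
    orf_nt = len(orf)
    coverage = rng.uniform(0.85, 0.95)
    total = int(round(orf_nt / coverage))
    flank = total - orf_nt
    left = int(rng.integers(0, flank + 1))
    return _random_seq(rng, left) + orf + _random_seq(rng, flank - left)


def _noncoding_sequence(rng: np.random.Generator, length: int,
                        max_orf_aa: int = 100, max_coverage: float = 0.5,
                        max_tries: int = 2000) -> str:
    """Random sequence whose six-frame ORFs are all short.

    Rejection-samples until the longest ORF is both <= ``max_orf_aa``
    and covers <= ``max_coverage`` of the transcript, keeping the base
    composition unbiased.  The coverage cap keeps generated noncoding
    transcripts clearly on the noncoding side of both coding-potential
    boundaries.
    """
    aa_cap = min(max_orf_aa, int((max_coverage * length - 3) // 3))
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if longest_orf(seq) <= aa_cap:
            return seq
    raise RuntimeError(
        f"could not sample a noncoding sequence of length {length} "
        f"with ORF <= {aa_cap} aa"
    )


def simulate_transcripts(
    n_by_class: Mapping[str, int],
    length_range: tuple[int, int] = (250, 1200),
    seed: int = 0,
) -> tuple[TranscriptSet, SimTruth]:
    """Generate a mixed coding/noncoding transcript set with truth labels.

    Classes: ``coding`` (embedded ATG..stop ORF > 100 aa covering most
    of the transcript), ``lncRNA`` / ``pri_miRNA`` / ``other_ncRNA``
    (>= 200 nt, all six-frame ORFs <= 100 aa), ``short_nc`` (< 200 nt).
    Deterministic under a fixed seed.
    """
    unknown = set(n_by_class) - set(TRANSCRIPT_CLASSES)
    if unknown:
        raise ValueError(f"unknown transcript classes: {sorted(unknown)}")
    if any(n < 0 for n in n_by_class.values()):
        raise ValueError("class counts must be >= 0")
    lmin, lmax = length_range
    if lmin < 50:
        raise ValueError("length_range minimum must be >= 50")
    if n_by_class.get("coding", 0) and lmax < 340:
        raise ValueError(
            "coding transcripts need length_range max >= 340 nt "
            "(ORF > 100 aa plus flanks)"
        )
    rng = _rng(seed, 0)
    records: dict[str, str] = {}
    truth = SimTruth()
    prefixes = {"coding": "cod", "lncRNA": "lnc", "pri_miRNA": "pmir",
                "other_ncRNA": "ncr", "short_nc": "srt"}
    nc_min = max(200, lmin)
    for cls in TRANSCRIPT_CLASSES:
        for i in range(n_by_class.get(cls, 0)):
            tid = f"{prefixes[cls]}_{i:04d}"
            if cls == "coding":
                seq = _coding_sequence(rng)
            elif cls == "short_nc":
                # below the 200-nt filter regardless of the main range
                length = int(rng.integers(min(max(50, lmin), 150), 200))
                seq = _noncoding_sequence(rng, length)
            else:
                length = int(rng.integers(nc_min, max(lmax, nc_min + 1) + 1))
                seq = _noncoding_sequence(rng, length)
            records[tid] = seq
            truth.transcript_class[tid] = cls
    return TranscriptSet(records), truth


def _evalue(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** (-rng.uniform(lo_exp, hi_exp)))


def simulate_hits(
    truth: SimTruth, seed: int = 0, known_fraction: float = 0.5
) -> HitTable:
    """BLAST-style evidence consistent with the planted transcript classes.

    Coding transcripts get protein-database hits passing E < 1e-5;
    pri-miRNAs get miRNA-family hits and other structural ncRNAs get
    non-miRNA Rfam hits, both passing (E < 1e-5, identity > 90);
    a ``known_fraction`` of lncRNAs (rounded, chosen at random) get
    known-lncRNA database hits and are recorded in
    ``truth.known_lncrna``; everything else hits nothing.
    """
    if not 0.0 <= known_fraction <= 1.0:
        raise ValueError("known_fraction must be in [0, 1]")
    rng = _rng(seed, 1)
    rows = []
    by_class: dict[str, list[str]] = {}
    for tid, cls in truth.transcript_class.items():
        by_class.setdefault(cls, []).append(tid)

    protein_dbs = ("nr", "swissprot", "cc_protein")
    for tid in by_class.get("coding", []):
        for _ in range(int(rng.integers(1, 3))):
            rows.append({
                "query_id": tid,
                "subject_id": f"prot_{rng.integers(0, 10**6):06d}",
                "db_label": str(rng.choice(protein_dbs)),
                "percent_identity": float(rng.uniform(75, 99.5)),
                "evalue": _evalue(rng, 10, 60),
            })
    for tid in by_class.get("pri_miRNA", []):
        db = str(rng.choice(("mirbase", "rfam")))
        subject = (f"mir-{rng.integers(1, 500)}" if db == "mirbase"
                   else f"RF{rng.integers(1, 3000):05d}_mir-family")
        rows.append({
            "query_id": tid, "subject_id": subject, "db_label": db,
            "percent_identity": float(rng.uniform(91, 99.5)),
            "evalue": _evalue(rng, 6, 30),
        })
    structural = ("tRNA", "rRNA_5S", "snoRNA", "snRNA")
    for tid in by_class.get("other_ncRNA", []):
        rows.append({
            "query_id": tid,
            "subject_id": f"RF{rng.integers(1, 3000):05d}_"
                          f"{rng.choice(structural)}",
            "db_label": "rfam",
            "percent_identity": float(rng.uniform(91, 99.5)),
            "evalue": _evalue(rng, 6, 30),
        })
    lncs = by_class.get("lncRNA", [])
    n_known = int(round(known_fraction * len(lncs)))
    known = (list(rng.choice(lncs, size=n_known, replace=False))
             if n_known else [])
    truth.known_lncrna = set(known)
    for tid in known:
        rows.append({
            "query_id": tid,
            "subject_id": f"NONBRA{rng.integers(0, 10**6):06d}",
            "db_label": "noncode",
            "percent_identity": float(rng.uniform(91, 99.5)),
            "evalue": _evalue(rng, 6, 30),
        })
    return HitTable.from_rows(rows)


@dataclass(frozen=True)
class DeEntry:
    """Planted differential expression: n genes at one FC in one condition."""

    condition: str
    fold_change: float
    n_genes: int


@dataclass(frozen=True)
class CoexprSpec:
    """Planted correlation structure for target-linkage tests."""

    n_positive: int = 0
    n_negative: int = 0
    n_decoys: int = 0
    decoy_max_abs_pcc: float = 0.8


def simulate_expression(
    design: pd.DataFrame | None = None,
    n_background: int = 200,
    de_spec: Sequence[DeEntry] | None = None,
    pattern_spec: Mapping[str, int] | None = None,
    coexpr_spec: CoexprSpec | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    control_condition: str = "T25",
    condition_order: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Replicated FPKM matrix with planted DE, patterns and correlations.

    Per-gene per-condition mean FPKM is drawn log-normally; replicate
    values are mean x 2**N(0, noise_sd) (``noise_sd`` in log2 units, so
    0 gives exact condition means).  Background genes jitter between
    conditions by factors inside (0.8, 1.25), keeping their step and
    treatment fold changes strictly inside (0.5, 2) at zero noise.

    * ``de_spec`` entries plant genes whose mean in one condition is
      base x FC (FC > 0, up when >= 2, down when <= 0.5);
    * ``pattern_spec`` maps course patterns (e.g. "UMD") to gene counts;
      U steps multiply the mean by 3, D by 1/3, M by a factor in
      (0.75, 1.3), so the letters survive the pseudocounted classifier;
    * ``coexpr_spec`` plants source->target pairs sharing a latent
      log2 profile (target = 2**(a +/- z) - 1, so correlation on
      log2(FPKM + 1) is exactly +/-1 at zero noise) plus decoy genes
      rejection-sampled to correlate with no source beyond
      ``decoy_max_abs_pcc``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if design is None:
        design = default_design()
    conditions = (tuple(condition_order) if condition_order is not None
                  else tuple(dict.fromkeys(design["condition"])))
    rng = _rng(seed, 2)
    truth = SimTruth()
    mean_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    n_cond = len(conditions)
    cond_idx = {c: i for i, c in enumerate(conditions)}

    def _background_means(base: float) -> np.ndarray:
        return base * rng.uniform(0.8, 1.25, size=n_cond)

    # planted DE genes
    for k, entry in enumerate(de_spec or []):
        if entry.fold_change <= 0:
            raise ValueError("planted fold change must be > 0")
        if entry.condition not in cond_idx:
            raise ValueError(f"unknown condition {entry.condition!r}")
        for i in range(entry.n_genes):
            gid = f"de{k}_{i:04d}"
            base = float(rng.uniform(5, 50))
            means = np.full(n_cond, base)
            means[cond_idx[entry.condition]] = base * entry.fold_change
            gene_ids.append(gid)
            mean_rows.append(means)
            direction = ("up" if entry.fold_change >= 2
                         else "down" if entry.fold_change <= 0.5 else "none")
            truth.de_status.setdefault(gid, {})[entry.condition] = (
                direction, entry.fold_change
            )

    # planted course-pattern genes (course = first 4 conditions)
    course_len = min(4, n_cond)
    for pattern, count in (pattern_spec or {}).items():
        if len(pattern) != course_len - 1 or set(pattern) - set("UDM"):
            raise ValueError(f"invalid pattern {pattern!r}")
        for i in range(count):
            gid = f"pat{pattern}_{i:04d}"
            base = float(rng.uniform(100, 500))
            means = np.empty(n_cond)
            means[0] = base
            for s, letter in enumerate(pattern):
                factor = {"U": 3.0, "D": 1.0 / 3.0,
                          "M": float(rng.uniform(0.75, 1.3))}[letter]
                means[s + 1] = means[s] * factor
            for j in range(course_len, n_cond):
                means[j] = base * rng.uniform(0.8, 1.25)
            gene_ids.append(gid)
            mean_rows.append(means)
            truth.patterns[gid] = pattern

    # planted coexpression structure on the log2(FPKM + 1) scale
    if coexpr_spec is not None:
        spec = coexpr_spec
        source_profiles: list[np.ndarray] = []

        def _fresh_profile() -> np.ndarray:
            # keep every latent profile below the decoy correlation bound
            # against all earlier sources, so the planted pairs are the
            # only high-correlation structure in the matrix
            for _ in range(5000):
                z = rng.uniform(2, 8, size=n_cond)
                if all(
                    abs(np.corrcoef(z, zs)[0, 1]) <= spec.decoy_max_abs_pcc
                    for zs in source_profiles
                ):
                    return z
            raise RuntimeError("could not sample an uncorrelated profile")

        for k in range(spec.n_positive + spec.n_negative):
            z = _fresh_profile()
            sign = "positive" if k < spec.n_positive else "negative"
            sid, tid = f"src_{k:04d}", f"tgt_{k:04d}"
            shift = float(rng.uniform(-1, 1))
            zt = z + shift if sign == "positive" else (10.0 - z) + shift
            gene_ids.append(sid)
            mean_rows.append(2.0 ** z - 1.0)
            gene_ids.append(tid)
            mean_rows.append(2.0 ** zt - 1.0)
            truth.coexpr_pairs.append((sid, tid, sign))
            source_profiles.append(z)
        for k in range(spec.n_decoys):
            z = _fresh_profile()
            gid = f"dcy_{k:04d}"
            gene_ids.append(gid)
            mean_rows.append(2.0 ** z - 1.0)
            truth.decoys.append(gid)

    # background: log-normal base, bounded between-condition jitter
    for i in range(n_background):
        base = float(2.0 ** rng.normal(3.0, 2.0))
        gene_ids.append(f"bg_{i:04d}")
        mean_rows.append(_background_means(base))

    means = np.vstack(mean_rows) if mean_rows else np.empty((0, n_cond))
    libs = [l for l in design.index]
    lib_cond = [cond_idx[design.loc[l, "condition"]] for l in libs]
    values = np.empty((len(gene_ids), len(libs)))
    for j, ci in enumerate(lib_cond):
        eps = rng.normal(0.0, noise_sd, size=len(gene_ids)) if noise_sd else 0.0
        values[:, j] = means[:, ci] * (2.0 ** eps)
    frame = pd.DataFrame(values, index=gene_ids, columns=libs)
    matrix = ExpressionMatrix(frame, design.copy(), conditions)
    return matrix, truth
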