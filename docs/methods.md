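# Methods

This note documents the models and procedures implemented in `temptrans`,
the parameters that matter, the synthetic-data generator's assumptions,
and the numerical choices made where the design was genuinely open.

## lncRNA filter cascade

Transcripts from a de novo assembly carry no genome coordinates, so lncRNA
identification is purely sequence- and evidence-based. The cascade applies
five filters in a fixed order; a transcript removed at one stage receives
no decisions for later stages, and every transcript gets exactly one final
class:

1. **Annotation** — any protein-database hit at E < 10⁻⁵ ⇒
   `annotated_coding`. Threshold comparisons throughout the package are
   strict (`<`, `>`) exactly as conventionally printed.
2. **Length** — shorter than 200 nt ⇒ `too_short` (the defining length
   bound of lncRNAs).
3. **Dual coding potential** — a transcript must be called noncoding by
   *both* channels (conjunction): the intrinsic channel below 0 and the
   evidence channel below −1. Survivor counts under a conjunctive filter
   are the conservative reading of combining two independent methods.
4. **ORF size** — longest six-frame ORF > 100 aa ⇒ `orf_coding`.
5. **Triage** — hits against noncoding databases, filtered at E < 10⁻⁵
   and identity > 90 %: miRNA-family hit (miRBase, or an Rfam family whose
   accession names a miR family) ⇒ `pri_miRNA`; other Rfam hit ⇒
   `other_ncRNA`; known-lncRNA database hit ⇒ `lncRNA_known`; nothing ⇒
   `lncRNA_novel`. Precedence miRNA > other structural > known-lncRNA
   mirrors the practice of extracting pri-miRNAs before lncRNAs.

**ORF definition.** ATG-initiated, in-frame stop required, all six frames,
stop codon not counted in the amino-acid length; ORFs running off the
transcript end are not counted. Codons containing ambiguity characters
(N) invalidate any ORF they fall inside, so N-rich stretches never
contribute coding signal.

**Coding-potential scorers.** The original tools behind the two channels
are SVM/codon-usage classifiers whose internals are out of scope here;
the built-in scorers are transparent, deterministic calibrations that
preserve the decision-boundary conventions (0 and −1), and external score
tables can be substituted via `cnci_scores=` / `cpc_scores=` (or
`--cnci-scores/--cpc-scores` on the CLI) for fidelity with the tools:

* intrinsic channel: `2·(coverage − 0.65) + 0.2·(bias − 0.5)`, where
  *coverage* is the fraction of the transcript spanned by the longest ORF
  (stop included) and *bias* ∈ [0, 1] is a Fickett-style codon-position
  asymmetry statistic. Coverage ≥ 0.8 guarantees a positive score;
  coverage ≤ 0.5 guarantees a negative one, for any bias value.
* evidence channel: `10·(coverage − 0.65) + 0.3·tanh(aa/100 − 1)`,
  clamped to ≥ 0 when any qualifying protein hit exists (hard evidence
  of coding ability). Coverage ≤ 0.5 with ORF ≤ 100 aa forces < −1;
  a 150-aa ORF covering 90 % of a transcript scores above −1.

These margins (0.5 / 0.8 coverage) are exactly the margins the synthetic
generator enforces, so on generated data every transcript sits clearly on
one side of each boundary and the cascade recovers planted classes
exactly. Real transcripts with intermediate ORF coverage will land near
the boundaries, where these simple scorers are much weaker than the
original tools — that is the main limitation of the built-in channels.

## Differential expression

The q statistic emulates the contract of nonparametric noise-dominance DE
callers for replicate-poor RNA-seq rather than any tool's internals
(length-dependent smoothing and simulated-replicate machinery are
deliberately out of scope):

* **Noise cloud** — for every condition with ≥ 2 replicates, every ordered
  replicate pair and every gene contributes (|M|, D) with
  M = log₂((a + c)/(b + c)) and D = |a − b| on FPKM, pooled across genes
  and conditions.
* **Signal** — per gene and treatment-vs-control comparison, the same
  quantities on condition-mean FPKM.
* **q** — the fraction of noise pairs strictly dominated in both
  coordinates. q is monotone in |M| and D and equals a brute-force double
  loop by construction (property-tested).
* **Call** — up iff FC ≥ 2 and q > 0.8; down iff FC ≤ 0.5 and q > 0.8.
  The fold-change thresholds are **inclusive** (≥ 2, ≤ 0.5).

Defaults and rationale: pseudocount c = 1 on FPKM before every ratio
(FPKM of exactly 0 occurs in real tables and must not produce infinite
fold changes; configurable); condition summary = arithmetic mean of
replicate FPKM; direction consistency is *not* required for membership in
multi-treatment overlap sets, but per-treatment directions are reported.
Degenerate case: with zero replicate noise the noise cloud is all (0, 0)
pairs, so any gene whose means differ at all gets q = 1 and the FC
threshold alone decides — this is what makes zero-noise recovery exact.

Temperature-specific expressed transcripts (SETs) use mean FPKM > 0 in
exactly one condition; the mean (not every replicate) is the detection
criterion.

## Temperature-course patterns

Steps run along the cold course 25→4→0→−4 °C with the higher temperature
as denominator; U iff FC ≥ 2, D iff FC ≤ 0.5, M otherwise, FC
pseudocounted as in DE calling. Letters are fold-change-only by default:
the pattern census is a census of *all* genes, most of which are
non-significant maintainers. The census always reports all 3^(k−1)
classes, zeros included, and conserves the gene count. The heat condition
(44 °C) is excluded from the course by default — the course models the
cold decrease.

## Coexpression networks

Profiles are log₂(FPKM + 1) across all libraries by default (raw mode
available); correlations are Pearson. Thresholds are strict and follow
the field's tiers: |PCC| > 0.8 for TF interaction networks (absolute
value, since observed TF networks contain negative edges), PCC > 0.9 for
target linkage (signed by default, |PCC| via flag), |PCC| > 0.95 for
lncRNA–mRNA networks. Computed correlations are rounded to 10 decimals
before threshold comparison so strict boundaries do not hinge on last-ulp
floating-point noise. Edges are undirected, deduplicated, ordered
node_a < node_b and emitted in pair-lexicographic order; components are
reported largest-first with lexicographic tie-break. Zero-variance
profiles yield undefined (missing) correlations, never 0, and never form
edges. Whether correlations should run over all 15 libraries or the 5
condition means is not determined by the analysis being emulated; both
modes exist (`restrict_conditions=`) and neither is asserted as canonical.

## Enrichment

Upper-tail hypergeometric per term (computed via the scipy survival
function, equal to the exact combinatorial sum — oracle-tested to N = 60),
BH adjustment across all tested terms (BY available), significance at
q < alpha strictly, default alpha 0.01 with all background genes as the
universe. "Enriched genes" for intersection counting = the union of
DEG-set genes annotated to any significant term; this definition is a
package choice since the quantity is not standardised.

## Synthetic-data generator

The generator produces the study-shaped data the pipeline consumes, with
planted truth:

* **Transcripts** — coding: one embedded ATG…stop ORF of 110–250 aa
  covering 85–95 % of the transcript; noncoding (lncRNA, pri-miRNA,
  other ncRNA): ≥ 200 nt, rejection-sampled until all six-frame ORFs are
  ≤ 100 aa *and* cover ≤ 50 % of the length (rejection rather than
  post-editing keeps base composition unbiased); short noncoding:
  50–199 nt. The coverage margins match the scorer calibrations above.
* **Hits** — protein hits (E between 10⁻¹⁰ and 10⁻⁶⁰, identity 75–99.5 %)
  for every coding transcript; miRNA-family and structural-family hits
  (identity 91–99.5 %, E < 10⁻⁶) for the respective classes; a configured
  fraction of lncRNAs receive known-lncRNA hits.
* **Expression** — per-gene per-condition mean FPKM; replicates are
  mean × 2^N(0, σ) with σ (`noise_sd`) in log₂ units, default 0.5. At
  1000 genes this yields within-condition replicate correlations of
  log₂ FPKM around 0.93–0.99, comfortably in the > 0.85 concordance
  regime of well-replicated experiments; σ = 0 gives exact means.
  The log-normal multiplicative noise model is a stand-in — no noise
  model is prescribed by the emulated analysis — chosen for positive
  support and realistic replicate concordance.
* **Planted DE** — base expression uniform in [5, 50]; the planted
  condition's mean is base × FC. Background genes jitter between
  conditions by factors in (0.8, 1.25), so their pseudocounted fold
  changes stay strictly inside (0.5, 2) at zero noise: at σ = 0 the DEG
  caller recovers the planted set exactly, by construction.
* **Planted patterns** — course means start at base ∈ [100, 500]; U steps
  multiply by 3, D by 1/3, M by a factor in (0.75, 1.3). The M band is
  kept away from the 2×/0.5× boundaries so small noise cannot flip
  letters.
* **Planted correlations** — each source/target pair shares a latent
  log₂ profile z (uniform in [2, 8] per condition) with
  FPKM = 2^z − 1, so correlation on log₂(FPKM + 1) is exactly ±1 at zero
  noise. Every source profile and every decoy is rejection-sampled to
  |PCC| ≤ 0.8 against all earlier sources: with only five conditions,
  unconstrained random profiles exceed |PCC| > 0.95 by chance often
  enough to contaminate exact-recovery experiments, so bounding
  background correlation is part of planting the structure.

All three generators are deterministic under a fixed integer seed
(per-component sub-streams derived from (seed, tag) pairs).

**What passing on synthetic data does and does not show.** The generator
plants classes with clear margins on every filter boundary and noise-free
options for every recovery property; it does not emulate assembly
artifacts, chimeric transcripts, codon-usage realism, length-dependent
FPKM bias, or borderline coding potential. Exact truth recovery therefore
validates the *logic* of the cascade, the caller and the network code,
not their discriminative power on boundary cases in real data.

## Bundled panels and reproduction

Two small worked-input panels ship as package data: condition-mean FPKM
for ten all-treatment-responsive genes (with reported direction and
annotation) and per-comparison log₂ ratios and q values for 17
cold-responsive TF transcripts. `scripts/acceptance.py` recomputes from
these, at run time: the number of panel genes with a consistent direction
across all four treatment comparisons (and the up/down split), and the
number of TF records passing |log₂FC| ≥ 1 and q > 0.8 in all three cold
comparisons. Problem sizes: the test suite runs the cascade on 500
generated transcripts and the recovery properties on matrices of tens to
a thousand genes — sizes at which every property is exact and the whole
suite completes in seconds.
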