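"""Hypergeometric term-enrichment testing with BH correction.

A DEG set is tested term-by-term against a background gene universe:
for a term annotating K of N background genes, observing k annotated
genes in a DEG set of size n has upper-tail probability
P(X >= k) under X ~ Hypergeometric(N, K, n).  P-values are adjusted
across all tested terms by Benjamini-Hochberg (optionally
Benjamini-Yekutieli); terms are significant at q < alpha (strict).

Cross-treatment intersections of enriched gene sets and the AND
combination across annotation sources (GO and KEGG) are provided for
overlap reporting.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_upper",
    "enrich",
    "enriched_genes",
    "enrichment_intersections",
    "combine_sources",
]


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    k = marked genes observed in the draw.  Computed via the stable
    survival function; inconsistent counts raise.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k > 0 and k > min(n, K):
        raise ValueError("k exceeds min(n, K)")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    de_set: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.01,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Test every term for over-representation in the DEG set.

    ``term_map`` maps term id -> annotated gene ids.  Genes outside the
    background are an error for the DEG set and silently dropped from
    term annotations.  Returns one row per term with K >= 1 in the
    background, ordered by p then term id, with BH-adjusted q and a
    strict ``significant = q < alpha`` flag.
    """
    bg = set(background)
    de = set(de_set)
    outside = de - bg
    if outside:
        raise ValueError(f"DE genes outside background: {sorted(outside)[:5]}")
    N, n = len(bg), len(de)
    rows = []
    for term, genes in term_map.items():
        annotated = set(genes) & bg
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & de)
        rows.append({
            "term_id": term, "k": k, "n": n, "K": K, "N": N,
            "p": hypergeom_upper(k, n, K, N),
            "genes": sorted(annotated & de),
        })
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "k", "n", "K", "N", "p", "q",
                     "significant", "genes"]
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method=method)[1]
    out["significant"] = out["q"] < alpha
    out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[["term_id", "k", "n", "K", "N", "p", "q", "significant", "genes"]]


def enriched_genes(results: pd.DataFrame) -> set[str]:
    """Union of DEG-set genes annotated to any significant term."""
    out: set[str] = set()
    for _, row in results[results["significant"]].iterrows():
        out.update(row["genes"])
    return out


def enrichment_intersections(
    sets: Mapping[str, Iterable[str]]
) -> dict[frozenset, int]:
    """Exact venn-region sizes over named enriched gene sets.

    Returns a mapping from every non-empty combination of set names to
    the number of genes present in exactly those sets.
    """
    named = {k: set(v) for k, v in sets.items()}
    if len(named) < 2:
        raise ValueError("need >= 2 sets")
    names = list(named)
    regions: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = 0
    for gene in set().union(*named.values()):
        members = frozenset(nm for nm in names if gene in named[nm])
        regions[members] += 1
    return regions


def combine_sources(
    per_source_enriched: Mapping[str, Iterable[str]], mode: str = "and"
) -> set[str]:
    """Combine enriched gene sets across annotation sources.

    "and": gene must be enriched in every source (e.g. both GO and
    KEGG); "or": union.
    """
    sets = [set(v) for v in per_source_enriched.values()]
    if not sets:
        return set()
    if mode == "and":
        return set.intersection(*sets)
    if mode == "or":
        return set.union(*sets)
    raise ValueError(f"unknown mode {mode!r}")
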