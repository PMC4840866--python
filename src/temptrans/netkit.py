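"""Pearson-correlation coexpression networks.

Edges connect gene pairs whose expression profiles correlate beyond a
threshold: |PCC| > 0.8 for transcription-factor interaction networks,
PCC > 0.9 for stress-gene target linkage, |PCC| > 0.95 for the
lncRNA-mRNA network.  Profiles are log2(FPKM + 1) across all libraries
by default; a condition-restricted mode supports per-treatment
networks, and target linkage can intersect hits across several
condition subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "CoexpressionEdge",
    "NetworkCluster",
    "pcc",
    "build_network",
    "sign_census",
    "components",
    "link_targets",
    "edges_to_frame",
    "to_graphml",
]


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when undefined.

    Requires equal lengths >= 3.  A zero-variance vector makes the
    correlation undefined, reported as NaN rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected coexpression edge; node_a < node_b lexicographically."""

    node_a: str
    node_b: str
    pcc: float
    sign: str        # "positive" iff pcc > 0
    pair_type: str


def _profiles(
    matrix: ExpressionMatrix,
    transform: str,
    restrict_conditions: Sequence[str] | None,
) -> pd.DataFrame:
    m = matrix
    if restrict_conditions is not None:
        m = matrix.subset_conditions(list(restrict_conditions))
    vals = m.values
    if transform == "log2p1":
        return np.log2(vals + 1.0)
    if transform == "raw":
        return vals
    raise ValueError(f"unknown transform {transform!r}")


def _pair_type(a: str, b: str, node_classes: Mapping[str, str] | None) -> str:
    if node_classes is None:
        return "unclassified"
    ca, cb = node_classes.get(a, "?"), node_classes.get(b, "?")
    return "-".join(sorted((ca, cb)))


def build_network(
    matrix: ExpressionMatrix,
    within: Iterable[str] | None = None,
    between: tuple[Iterable[str], Iterable[str]] | None = None,
    abs_threshold: float = 0.95,
    transform: str = "log2p1",
    restrict_conditions: Sequence[str] | None = None,
    node_classes: Mapping[str, str] | None = None,
    signed_threshold: bool = False,
) -> list[CoexpressionEdge]:
    """Coexpression edges where |PCC| (or PCC) strictly exceeds a threshold.

    Pairs come either from ``within`` one node set (all unordered
    pairs) or ``between`` two sets (cross pairs only, shared nodes
    never self-paired).  Edges are deduplicated, ordered node_a <
    node_b and listed in pair-lexicographic order.  Zero-variance
    profiles never form edges.  ``signed_threshold`` applies the
    threshold to the signed PCC (positive edges only) instead of |PCC|.
    """
    if (within is None) == (between is None):
        raise ValueError("specify exactly one of within= or between=")
    prof = _profiles(matrix, transform, restrict_conditions)
    if within is not None:
        nodes = list(dict.fromkeys(within))
        _check_nodes(nodes, prof)
        idx = {n: i for i, n in enumerate(nodes)}
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        mat = prof.loc[nodes].to_numpy(dtype=float)
        corr = _corr_matrix(mat)
        get = lambda a, b: corr[idx[a], idx[b]]
    else:
        set_a = list(dict.fromkeys(between[0]))
        set_b = list(dict.fromkeys(between[1]))
        _check_nodes(set_a + set_b, prof)
        pairs = [(a, b) for a in set_a for b in set_b if a != b]
        seen = set()
        uniq = []
        for a, b in pairs:
            key = tuple(sorted((a, b)))
            if key not in seen:
                seen.add(key)
                uniq.append((a, b))
        pairs = uniq
        nodes = list(dict.fromkeys(set_a + set_b))
        idx = {n: i for i, n in enumerate(nodes)}
        corr = _corr_matrix(prof.loc[nodes].to_numpy(dtype=float))
        get = lambda a, b: corr[idx[a], idx[b]]

    edges = []
    for a, b in pairs:
        r = get(a, b)
        if np.isnan(r):
            continue
        passed = r > abs_threshold if signed_threshold else abs(r) > abs_threshold
        if not passed:
            continue
        na, nb = sorted((a, b))
        edges.append(CoexpressionEdge(
            node_a=na, node_b=nb, pcc=float(r),
            sign="positive" if r > 0 else "negative",
            pair_type=_pair_type(na, nb, node_classes),
        ))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def _check_nodes(nodes: Sequence[str], prof: pd.DataFrame) -> None:
    missing = [n for n in nodes if n not in prof.index]
    if missing:
        raise KeyError(f"nodes absent from matrix: {missing[:10]}")


def _corr_matrix(mat: np.ndarray) -> np.ndarray:
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    # strict-threshold comparisons must not hinge on last-ulp noise
    return np.round(corr, 10)


def sign_census(edges: Sequence[CoexpressionEdge]) -> dict:
    """Counts and proportions of positive vs negative edges."""
    n_pos = sum(1 for e in edges if e.sign == "positive")
    n_neg = sum(1 for e in edges if e.sign == "negative")
    total = n_pos + n_neg
    return {
        "n_positive": n_pos,
        "n_negative": n_neg,
        "prop_positive": n_pos / total if total else float("nan"),
        "prop_negative": n_neg / total if total else float("nan"),
    }


@dataclass
class NetworkCluster:
    members: tuple[str, ...]
    n_edges: int
    n_positive: int
    n_negative: int


def components(edges: Sequence[CoexpressionEdge]) -> list[NetworkCluster]:
    """Connected components of the edge graph, largest first.

    Ordering is deterministic: decreasing size, ties broken by the
    lexicographically smallest member.  Isolated nodes cannot occur
    (nodes exist only through edges).
    """
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.node_a, e.node_b, pcc=e.pcc, sign=e.sign)
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        sub = g.subgraph(comp)
        n_pos = sum(1 for *_, d in sub.edges(data=True) if d["sign"] == "positive")
        clusters.append(NetworkCluster(
            members=members,
            n_edges=sub.number_of_edges(),
            n_positive=n_pos,
            n_negative=sub.number_of_edges() - n_pos,
        ))
    clusters.sort(key=lambda c: (-len(c.members), c.members[0]))
    return clusters


def link_targets(
    matrix: ExpressionMatrix,
    source_set: Iterable[str],
    candidate_set: Iterable[str],
    min_pcc: float = 0.9,
    use_abs: bool = False,
    transform: str = "log2p1",
    condition_subsets: Sequence[Sequence[str]] | None = None,
) -> dict[str, list[str]]:
    """Link each source gene to candidates correlating beyond ``min_pcc``.

    The comparison is strict on PCC (or |PCC| with ``use_abs``).  With
    ``condition_subsets`` the linkage is computed once per subset of
    conditions and a candidate must pass in every subset (intersection
    mode, e.g. targets supported under each cold treatment).
    Source and candidate sets must be disjoint.
    """
    sources = list(dict.fromkeys(source_set))
    candidates = list(dict.fromkeys(candidate_set))
    if set(sources) & set(candidates):
        raise ValueError("source and candidate sets must be disjoint")

    def _one(restrict: Sequence[str] | None) -> dict[str, set[str]]:
        prof = _profiles(matrix, transform, restrict)
        _check_nodes(sources + candidates, prof)
        src = prof.loc[sources].to_numpy(dtype=float)
        cand = prof.loc[candidates].to_numpy(dtype=float)
        links: dict[str, set[str]] = {s: set() for s in sources}
        src_sd = src.std(axis=1)
        cand_sd = cand.std(axis=1)
        src_c = src - src.mean(axis=1, keepdims=True)
        cand_c = cand - cand.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (src_c @ cand_c.T) / (
                np.outer(src_sd, cand_sd) * src.shape[1]
            )
        corr = np.round(corr, 10)
        for i, s in enumerate(sources):
            for j, t in enumerate(candidates):
                r = corr[i, j]
                if np.isnan(r):
                    continue
                val = abs(r) if use_abs else r
                if val > min_pcc:
                    links[s].add(t)
        return links

    if condition_subsets is None:
        merged = _one(None)
    else:
        runs = [_one(list(sub)) for sub in condition_subsets]
        merged = {
            s: set.intersection(*(run[s] for run in runs)) for s in sources
        }
    return {s: sorted(ts) for s, ts in merged.items()}


def edges_to_frame(edges: Sequence[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"node_a": e.node_a, "node_b": e.node_b, "pcc": e.pcc,
          "sign": e.sign, "pair_type": e.pair_type} for e in edges],
        columns=["node_a", "node_b", "pcc", "sign", "pair_type"],
    )


def to_graphml(edges: Sequence[CoexpressionEdge], path: str) -> None:
    """Export the edge list as GraphML for network viewers."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.node_a, e.node_b, pcc=e.pcc, sign=e.sign,
                   pair_type=e.pair_type)
    nx.write_graphml(g, path)
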