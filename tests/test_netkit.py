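import itertools
import math

import numpy as np
import pandas as pd
import pytest

from temptrans import netkit, simdata
from temptrans.core_io import ExpressionMatrix
from helpers import matrix_from_means


def brute_force_edges(values: pd.DataFrame, threshold: float):
    """All-pairs PCC loop, independent of the vectorised path."""
    edges = set()
    genes = list(values.index)
    for a, b in itertools.combinations(genes, 2):
        x, y = values.loc[a].to_numpy(), values.loc[b].to_numpy()
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) > threshold:
            edges.add(tuple(sorted((a, b))))
    return edges


class TestPcc:
    def test_exact_linearity(self):
        assert netkit.pcc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_anticorrelation(self):
        assert netkit.pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert netkit.pcc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_is_nan(self):
        assert math.isnan(netkit.pcc([1, 1, 1], [1, 2, 3]))

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            netkit.pcc([1, 2], [3, 4])


class TestBuildNetwork:
    def test_identical_profiles_positive_edge(self):
        means = pd.DataFrame(
            [[1, 5, 9, 2, 7]] * 2, index=["a", "b"],
            columns=["T25", "T4", "T0", "TM4", "T44"], dtype=float,
        )
        edges = netkit.build_network(matrix_from_means(means), within=["a", "b"],
                                     abs_threshold=0.95)
        assert len(edges) == 1
        assert edges[0].pcc == pytest.approx(1.0)
        assert edges[0].sign == "positive"

    def test_anticorrelated_pair_negative_edge(self):
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]], index=["a", "b"],
            columns=["T25", "T4", "T0", "TM4", "T44"], dtype=float,
        )
        edges = netkit.build_network(matrix_from_means(means), within=["a", "b"],
                                     abs_threshold=0.9, transform="raw")
        assert len(edges) == 1
        assert edges[0].sign == "negative"

    def test_threshold_is_strict(self):
        means = pd.DataFrame(
            [[1, 2, 3], [1, 3, 2]], index=["a", "b"],
            columns=["T25", "T4", "T0"], dtype=float,
        )  # raw pcc exactly 0.5
        edges = netkit.build_network(
            matrix_from_means(means), within=["a", "b"],
            abs_threshold=0.5, transform="raw",
        )
        assert edges == []

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(60)]
        means = pd.DataFrame(
            rng.uniform(0, 100, size=(60, 5)), index=genes,
            columns=["T25", "T4", "T0", "TM4", "T44"],
        )
        m = matrix_from_means(means)
        log_vals = np.log2(m.values + 1)
        for thr in (0.5, 0.8, 0.95):
            edges = netkit.build_network(m, within=genes, abs_threshold=thr)
            got = {(e.node_a, e.node_b) for e in edges}
            assert got == brute_force_edges(log_vals, thr)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        means = pd.DataFrame(rng.uniform(1, 50, size=(20, 5)), index=genes,
                             columns=["T25", "T4", "T0", "TM4", "T44"])
        m = matrix_from_means(means)
        base = netkit.build_network(m, within=genes, abs_threshold=0.8,
                                    transform="raw")
        shuffled = netkit.build_network(m, within=genes[::-1],
                                        abs_threshold=0.8, transform="raw")
        assert [(e.node_a, e.node_b, e.pcc) for e in base] == \
               [(e.node_a, e.node_b, e.pcc) for e in shuffled]


class TestSignCensus:
    def test_tf_network_proportions(self):
        edges = (
            [netkit.CoexpressionEdge(f"a{i}", f"b{i}", 0.9, "positive", "tf-tf")
             for i in range(82)]
            + [netkit.CoexpressionEdge(f"c{i}", f"d{i}", -0.9, "negative",
                                       "tf-tf") for i in range(13)]
        )
        census = netkit.sign_census(edges)
        assert census["n_positive"] == 82
        assert census["n_negative"] == 13
        assert census["prop_positive"] == pytest.approx(82 / 95)
        assert census["prop_negative"] == pytest.approx(13 / 95)

    def test_empty(self):
        census = netkit.sign_census([])
        assert census["n_positive"] == census["n_negative"] == 0
        assert math.isnan(census["prop_positive"])


class TestComponents:
    @staticmethod
    def _edge(a, b):
        return netkit.CoexpressionEdge(*sorted((a, b)), 1.0, "positive", "x")

    def test_two_clusters(self):
        comps = netkit.components(
            [self._edge("a", "b"), self._edge("b", "c"), self._edge("d", "e")])
        assert [len(c.members) for c in comps] == [3, 2]
        assert comps[0].members == ("a", "b", "c")

    def test_no_edges(self):
        assert netkit.components([]) == []

    def test_complete_graph(self):
        nodes = list("abcd")
        edges = [self._edge(a, b) for a, b in itertools.combinations(nodes, 2)]
        comps = netkit.components(edges)
        assert len(comps) == 1
        assert comps[0].n_edges == 6
        assert sum(len(c.members) for c in comps) == 4


class TestLinkTargets:
    def test_identical_profile_linked(self):
        means = pd.DataFrame(
            [[1, 5, 9, 2, 7], [1, 5, 9, 2, 7], [9, 1, 1, 9, 1]],
            index=["src", "same", "other"],
            columns=["T25", "T4", "T0", "TM4", "T44"], dtype=float,
        )
        links = netkit.link_targets(matrix_from_means(means), ["src"],
                                    ["same", "other"], min_pcc=0.9)
        assert links["src"] == ["same"]

    def test_planted_pairs_recovered_at_zero_noise(self):
        m, truth = simdata.simulate_expression(
            n_background=0,
            coexpr_spec=simdata.CoexprSpec(n_positive=8, n_negative=8,
                                           n_decoys=20),
            noise_sd=0.0, seed=21,
        )
        sources = [p[0] for p in truth.coexpr_pairs]
        candidates = [p[1] for p in truth.coexpr_pairs] + truth.decoys
        links = netkit.link_targets(m, sources, candidates, min_pcc=0.95,
                                    use_abs=True)
        got = {(s, t) for s, ts in links.items() for t in ts}
        assert got == {(s, t) for s, t, _ in truth.coexpr_pairs}
        # signed mode keeps only the positively planted pairs
        pos_links = netkit.link_targets(m, sources, candidates, min_pcc=0.95)
        got_pos = {(s, t) for s, ts in pos_links.items() for t in ts}
        assert got_pos == {(s, t) for s, t, sign in truth.coexpr_pairs
                           if sign == "positive"}

    def test_intersection_mode_requires_all_subsets(self):
        # target tracks the source only within the cold conditions
        means = pd.DataFrame(
            [[1, 5, 9, 2, 7], [1, 5, 9, 2, 7], [1, 5, 9, 2, 0.1]],
            index=["src", "always", "coldonly"],
            columns=["T25", "T4", "T0", "TM4", "T44"], dtype=float,
        )
        m = matrix_from_means(means)
        links = netkit.link_targets(
            m, ["src"], ["always", "coldonly"], min_pcc=0.95,
            condition_subsets=[["T25", "T4", "T0", "TM4"],
                               ["T0", "TM4", "T44"]],
        )
        assert links["src"] == ["always"]

    def test_overlapping_sets_rejected(self):
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5]], index=["g"],
            columns=["T25", "T4", "T0", "TM4", "T44"], dtype=float)
        with pytest.raises(ValueError):
            netkit.link_targets(matrix_from_means(means), ["g"], ["g"])


def test_graphml_round_trip(tmp_path):
    import networkx as nx
    edges = [netkit.CoexpressionEdge("a", "b", 0.97, "positive", "lnc-coding")]
    path = tmp_path / "net.graphml"
    netkit.to_graphml(edges, str(path))
    g = nx.read_graphml(path)
    assert g.has_edge("a", "b")
    assert g["a"]["b"]["pcc"] == pytest.approx(0.97)
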