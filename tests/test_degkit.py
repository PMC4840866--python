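import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temptrans import degkit, simdata
from temptrans.core_io import ExpressionMatrix
from helpers import matrix_from_means


def brute_force_q(abs_m, d, noise_pairs):
    """Independent dominance count: plain double-comparison loop."""
    dominated = sum(1 for nm, nd in noise_pairs if nm < abs_m and nd < d)
    return dominated / len(noise_pairs)


class TestNoiseDistribution:
    def test_identical_replicates_give_zero_pairs(self, toy_matrix):
        noise = degkit.noise_distribution(toy_matrix)
        assert np.all(noise.abs_m == 0)
        assert np.all(noise.d == 0)

    def test_hand_computed_pair(self):
        # 1 gene, one condition with replicates (4, 1), pseudocount 1:
        # M = log2(5/2), D = 3, both orders pooled
        design = simdata.default_design(("T25",), 2)
        vals = pd.DataFrame({"T25_R1": [4.0], "T25_R2": [1.0]}, index=["g"])
        m = ExpressionMatrix(vals, design, ("T25",))
        noise = degkit.noise_distribution(m)
        assert len(noise) == 2
        assert noise.abs_m == pytest.approx([np.log2(2.5)] * 2)
        assert noise.d == pytest.approx([3.0, 3.0])

    def test_pair_count_by_enumeration(self):
        # 2 conditions x 2 replicates x 10 genes -> 2*2*10 ordered entries
        rng = np.random.default_rng(0)
        design = simdata.default_design(("T25", "T4"), 2)
        vals = pd.DataFrame(
            rng.uniform(1, 50, size=(10, 4)),
            index=[f"g{i}" for i in range(10)], columns=design.index,
        )
        noise = degkit.noise_distribution(
            ExpressionMatrix(vals, design, ("T25", "T4")))
        assert len(noise) == 40

    def test_no_replicates_is_error(self):
        design = simdata.default_design(("T25", "T4"), 1)
        vals = pd.DataFrame(np.ones((3, 2)), index=list("abc"),
                            columns=design.index)
        with pytest.raises(ValueError, match="replicates"):
            degkit.noise_distribution(
                ExpressionMatrix(vals, design, ("T25", "T4")))


class TestDegProbability:
    def test_spec_worked_example(self):
        noise = degkit.NoiseDistribution(
            np.array([0.5, 2.0, 0.2]), np.array([1.0, 10.0, 4.0]))
        assert degkit.deg_probability(1.0, 5.0, noise) == pytest.approx(2 / 3)

    def test_extremes(self):
        noise = degkit.NoiseDistribution(np.array([1.0]), np.array([2.0]))
        assert degkit.deg_probability(0.0, 0.0, noise) == 0.0
        assert degkit.deg_probability(2.0, 3.0, noise) == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        pairs=st.lists(
            st.tuples(st.floats(0, 5), st.floats(0, 100)),
            min_size=1, max_size=1000,
        ),
        sig_m=st.floats(0, 6),
        sig_d=st.floats(0, 120),
    )
    def test_matches_brute_force(self, pairs, sig_m, sig_d):
        noise = degkit.NoiseDistribution(
            np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))
        assert degkit.deg_probability(sig_m, sig_d, noise) == pytest.approx(
            brute_force_q(sig_m, sig_d, pairs))

    @settings(max_examples=30, deadline=None)
    @given(
        sig_m=st.floats(0, 3), sig_d=st.floats(0, 50),
        bump_m=st.floats(0, 2), bump_d=st.floats(0, 20),
    )
    def test_monotone_in_signal(self, sig_m, sig_d, bump_m, bump_d):
        rng = np.random.default_rng(42)
        noise = degkit.NoiseDistribution(
            rng.uniform(0, 4, 200), rng.uniform(0, 60, 200))
        q0 = degkit.deg_probability(sig_m, sig_d, noise)
        q1 = degkit.deg_probability(sig_m + bump_m, sig_d + bump_d, noise)
        assert q1 >= q0


class TestCallDegs:
    def test_direction_from_worked_fold_changes(self):
        # condition means of two all-treatment-responsive genes; q forced
        means = pd.DataFrame(
            {"T25": [8.18, 139.12], "TM4": [191.73, 12.75]},
            index=["up_gene", "down_gene"],
        )
        m = matrix_from_means(means)
        q = pd.DataFrame({"TM4": [1.0, 1.0]}, index=means.index)
        calls = degkit.call_degs(m, "T25", q_values=q).set_index("gene_id")
        assert calls.loc["up_gene", "fc"] == pytest.approx(192.73 / 9.18)
        assert calls.loc["up_gene", "direction"] == "up"
        assert calls.loc["down_gene", "fc"] == pytest.approx(13.75 / 140.12)
        assert calls.loc["down_gene", "direction"] == "down"

    def test_fc_threshold_inclusive(self):
        means = pd.DataFrame({"T25": [1.0], "T4": [3.0]}, index=["g"])
        m = matrix_from_means(means)  # FC = 4/2 = 2 exactly
        q = pd.DataFrame({"T4": [0.9]}, index=["g"])
        calls = degkit.call_degs(m, "T25", q_values=q)
        assert calls.iloc[0]["direction"] == "up"

    def test_no_gene_both_up_and_down(self):
        m, _ = simdata.simulate_expression(
            n_background=30,
            de_spec=[simdata.DeEntry("T4", 4.0, 5)],
            noise_sd=0.3, seed=11,
        )
        calls = degkit.call_degs(m)
        per = calls.groupby(["gene_id", "comparison"])["direction"].nunique()
        assert (per == 1).all()

    def test_zero_noise_recovers_planted_set(self):
        m, truth = simdata.simulate_expression(
            n_background=40,
            de_spec=[simdata.DeEntry("T4", 4.0, 8),
                     simdata.DeEntry("T0", 0.25, 8)],
            noise_sd=0.0, seed=5,
        )
        calls = degkit.call_degs(m)
        called = {
            (r.gene_id, r.treatment)
            for r in calls.itertuples() if r.direction != "none"
        }
        planted = {
            (g, cond) for g, d in truth.de_status.items() for cond in d
        }
        assert called == planted
        directions = {(r.gene_id, r.treatment): r.direction
                      for r in calls.itertuples()}
        for g, d in truth.de_status.items():
            for cond, (direction, _) in d.items():
                assert directions[(g, cond)] == direction


class TestOverlap:
    def test_basic_sets(self):
        rep = degkit.overlap_analysis({"A": {"1", "2"}, "B": {"2", "3"}})
        assert rep.specific == {"A": 1, "B": 1}
        assert rep.shared_all == {"2"}
        assert rep.region_sizes[frozenset({"A", "B"})] == 1

    def test_identical_sets(self):
        rep = degkit.overlap_analysis({"A": {"1", "2"}, "B": {"1", "2"}})
        assert rep.specific == {"A": 0, "B": 0}
        assert len(rep.shared_all) == 2

    def test_disjoint_sets(self):
        rep = degkit.overlap_analysis(
            {t: {f"{t}{i}" for i in range(3)} for t in "ABCD"})
        assert rep.shared_all == set()
        assert all(rep.specific[t] == 3 for t in "ABCD")

    def test_regions_partition_universe(self):
        rng = np.random.default_rng(3)
        sets = {t: set(rng.choice(50, size=20)) for t in "ABC"}
        rep = degkit.overlap_analysis(sets)
        assert sum(rep.region_sizes.values()) == len(set().union(*sets.values()))
        for t in sets:
            total = sum(n for k, n in rep.region_sizes.items() if t in k)
            assert total == rep.totals[t]


class TestSpecificExpressed:
    def test_exclusive_condition(self):
        means = pd.DataFrame(
            {"T25": [0, 1, 0], "T4": [0, 1, 0], "T44": [5, 1, 0]},
            index=["only44", "everywhere", "nowhere"], dtype=float,
        )
        out = degkit.specific_expressed(matrix_from_means(means))
        assert out["gene_id"].tolist() == ["only44"]
        assert out["condition"].tolist() == ["T44"]
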