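import math

import numpy as np
import pytest

from conftest import random_discrete
from oracles import (
    family_likelihood_exact,
    log_fraction,
    network_log_score_exact,
)

from bnexpand.preprocess import DiscreteMatrix
from bnexpand.scoring import (
    Dag,
    FamilyCountTable,
    Scorer,
    family_counts,
    log_family_score,
    log_network_score,
)
from bnexpand.scoring import CyclicGraphError


class TestDag:
    def test_cycle_detected(self):
        with pytest.raises(CyclicGraphError):
            Dag(["a", "b"], {"a": {"b"}, "b": {"a"}})

    def test_self_parent_rejected(self):
        with pytest.raises(ValueError):
            Dag(["a"], {"a": {"a"}})

    def test_edges_children(self):
        d = Dag(["a", "b", "c"], {"b": {"a"}, "c": {"a", "b"}})
        assert d.edges() == [("a", "b"), ("a", "c"), ("b", "c")]
        assert d.children("a") == {"b", "c"}
        assert d.parents("c") == {"a", "b"}

    def test_equality_ignores_node_order(self):
        d1 = Dag(["a", "b"], {"b": {"a"}})
        d2 = Dag(["b", "a"], {"b": {"a"}})
        assert d1 == d2 and hash(d1) == hash(d2)

    def test_topological_order(self):
        d = Dag(["c", "a", "b"], {"b": {"a"}, "c": {"b"}})
        order = d.topological_order()
        assert order.index("a") < order.index("b") < order.index("c")


class TestFamilyCounts:
    def test_no_parents_tally(self):
        d = DiscreteMatrix(["x"], [f"s{i}" for i in range(6)],
                           np.array([[0, 0, 1, 2, 2, 2]]), arity=3)
        t = family_counts(d, "x", [])
        assert t.q_i == 1 and t.r_i == 3
        assert t.n_ijk.tolist() == [[2, 1, 3]]
        assert t.n_ij.tolist() == [6]

    def test_one_parent_tally(self, four_sample_data):
        t = family_counts(four_sample_data, "B", ["A"])
        assert t.q_i == 2
        assert t.n_ijk.tolist() == [[2, 0], [1, 1]]

    def test_zero_samples(self):
        d = DiscreteMatrix(["x", "y"], [], np.zeros((2, 0), dtype=int), arity=3)
        t = family_counts(d, "x", ["y"])
        assert t.n_ijk.sum() == 0
        assert t.n_ij.sum() == 0

    def test_unknown_gene_named(self, four_sample_data):
        with pytest.raises(KeyError, match="nope"):
            family_counts(four_sample_data, "nope", [])
        with pytest.raises(KeyError, match="nope"):
            family_counts(four_sample_data, "A", ["nope"])

    def test_child_not_own_parent(self, four_sample_data):
        with pytest.raises(ValueError):
            family_counts(four_sample_data, "A", ["A"])

    def test_mixed_radix_order(self):
        # parents sorted by id; first parent most significant
        states = np.array([[0, 1], [1, 0], [0, 1]])
        d = DiscreteMatrix(["c", "p2", "p1"], ["s1", "s2"], states, arity=2)
        t = family_counts(d, "c", ["p2", "p1"])
        assert t.parents == ("p1", "p2")
        # sample s1: p1=0,p2=1 -> config 1; s2: p1=1,p2=0 -> config 2
        assert t.n_ijk[1].tolist() == [1, 0]
        assert t.n_ijk[2].tolist() == [0, 1]


class TestLogFamilyScore:
    def test_single_observation(self):
        d = DiscreteMatrix(["x"], ["s1"], np.array([[1]]), arity=3)
        val = log_family_score(family_counts(d, "x", []))
        assert val == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_empty_data_is_zero(self):
        d = DiscreteMatrix(["x"], [], np.zeros((1, 0), dtype=int), arity=2)
        assert log_family_score(family_counts(d, "x", [])) == 0.0

    def test_worked_two_family_values(self, four_sample_data):
        fam_a = log_family_score(family_counts(four_sample_data, "A", []))
        fam_b = log_family_score(family_counts(four_sample_data, "B", ["A"]))
        assert fam_a == pytest.approx(math.log(1 / 30), abs=1e-12)
        assert fam_b == pytest.approx(math.log(1 / 3) + math.log(1 / 6), abs=1e-12)


class TestLogNetworkScore:
    def test_worked_edge_network(self, four_sample_data):
        net = log_network_score(Dag(["A", "B"], {"B": {"A"}}), four_sample_data)
        assert net.log_score == pytest.approx(-math.log(540), abs=1e-9)

    def test_worked_empty_graph(self, four_sample_data):
        net = log_network_score(Dag(["A", "B"]), four_sample_data)
        assert net.log_score == pytest.approx(-math.log(600), abs=1e-9)

    def test_zero_sample_score_is_zero(self):
        d = DiscreteMatrix(["x", "y"], [], np.zeros((2, 0), dtype=int), arity=3)
        net = log_network_score(Dag(["x", "y"], {"y": {"x"}}), d)
        assert net.log_score == 0.0

    def test_score_nonpositive(self):
        rng = np.random.default_rng(5)
        d = random_discrete(rng, 4, 8, 3)
        net = log_network_score(Dag(d.gene_ids, {"g1": {"g0"}}), d)
        assert net.log_score < 0.0

    def test_per_family_decomposition(self, four_sample_data):
        net = log_network_score(Dag(["A", "B"], {"B": {"A"}}), four_sample_data)
        assert sum(net.per_family_scores.values()) == pytest.approx(
            net.log_score, abs=1e-12
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        m = int(rng.integers(1, 9))
        arity = int(rng.integers(2, 4))
        data = random_discrete(rng, n, m, arity)
        # random parent sets from a random topological order
        order = list(rng.permutation(data.gene_ids))
        parent_sets = {
            g: {
                p
                for p in order[: order.index(g)]
                if rng.random() < 0.5
            }
            for g in order
        }
        net = log_network_score(Dag(data.gene_ids, parent_sets), data)
        states = {g: data.row(g).tolist() for g in data.gene_ids}
        expected = network_log_score_exact(states, parent_sets, arity)
        assert net.log_score == pytest.approx(expected, abs=1e-9)

    def test_family_oracle_direct(self, four_sample_data):
        got = log_family_score(family_counts(four_sample_data, "B", ["A"]))
        exact = family_likelihood_exact(
            four_sample_data.row("B").tolist(),
            [four_sample_data.row("A").tolist()],
            2,
        )
        assert got == pytest.approx(log_fraction(exact), abs=1e-12)


class TestDecomposability:
    def test_single_family_change(self):
        rng = np.random.default_rng(11)
        data = random_discrete(rng, 4, 8, 3)
        scorer = Scorer(data)
        dag = Dag(data.gene_ids, {"g1": {"g0"}, "g3": {"g2"}})
        before = scorer.score(dag)
        after = scorer.score(dag.with_parents("g3", {"g0", "g2"}))
        for g in ("g0", "g1", "g2"):
            assert after.per_family_scores[g] == before.per_family_scores[g]
        assert after.per_family_scores["g3"] != before.per_family_scores["g3"]

    def test_incremental_equals_full(self):
        rng = np.random.default_rng(12)
        data = random_discrete(rng, 4, 8, 3)
        scorer = Scorer(data)
        dag = Dag(data.gene_ids, {"g1": {"g0"}})
        modified = dag.with_parents("g2", {"g1"})
        incremental = (
            scorer.score(dag).log_score
            - scorer.family_score("g2", set())
            + scorer.family_score("g2", {"g1"})
        )
        assert incremental == pytest.approx(
            log_network_score(modified, data).log_score, abs=1e-9
        )


def test_copy_parent_beats_random_parent_majority():
    """Adding an exact-copy parent should usually fit better than adding an
    independent uniform-random parent (majority over 50 seeds)."""
    wins = 0
    trials = 50
    for seed in range(trials):
        rng = np.random.default_rng(1000 + seed)
        m = 30
        child = rng.integers(0, 3, size=m)
        copy_parent = child.copy()
        random_parent = rng.integers(0, 3, size=m)
        data = DiscreteMatrix(
            ["child", "copy", "rand"],
            [f"s{j}" for j in range(m)],
            np.vstack([child, copy_parent, random_parent]),
            arity=3,
        )
        s_copy = log_family_score(family_counts(data, "child", ["copy"]))
        s_rand = log_family_score(family_counts(data, "child", ["rand"]))
        if s_copy > s_rand:
            wins += 1
    assert wins > trials // 2


def test_scored_network_invariant_checked(four_sample_data):
    from bnexpand.scoring import ScoredNetwork

    with pytest.raises(ValueError):
        ScoredNetwork(
            dag=Dag(["A"]),
            log_score=-1.0,
            per_family_scores={"A": -2.0},
        )


def test_cyclic_input_rejected(four_sample_data):
    with pytest.raises(CyclicGraphError):
        log_network_score(
            Dag(["A", "B"], {"A": {"B"}, "B": {"A"}}), four_sample_data
        )
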