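import numpy as np
import pytest
from scipy.stats import chi2_contingency

from bnexpand.enrichment import fisher_pvalue
from bnexpand.preprocess import q3_discretize
from bnexpand.scoring import Dag
from bnexpand.search import SearchConfig, multi_restart_search
from bnexpand.synthetic import (
    GroundTruthModel,
    make_metadata,
    plant_regulator,
    sample_cpts,
    sample_dag,
    simulate,
)


class TestSampleDag:
    def test_edge_prob_zero_empty(self):
        dag = sample_dag(6, edge_prob=0.0, rng=np.random.default_rng(0))
        assert dag.edges() == []

    def test_edge_prob_one_full_forward(self):
        dag = sample_dag(3, max_parents=100, edge_prob=1.0,
                         rng=np.random.default_rng(0))
        assert len(dag.edges()) == 3

    def test_acyclic_over_many_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            sample_dag(5, edge_prob=0.5, rng=rng)  # Dag() raises on cycles

    def test_max_parents_respected(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            dag = sample_dag(8, max_parents=2, edge_prob=1.0, rng=rng)
            assert all(len(dag.parents(n)) <= 2 for n in dag.nodes)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sample_dag(0)
        with pytest.raises(ValueError):
            sample_dag(3, edge_prob=1.5)


class TestSampleCpts:
    def test_strength_one_is_deterministic(self):
        dag = sample_dag(4, edge_prob=0.5, rng=np.random.default_rng(3))
        model = sample_cpts(dag, strength=1.0, rng=np.random.default_rng(4))
        for node in dag.nodes:
            cpt = model.cpts[node]
            assert np.all(np.isin(cpt, (0.0, 1.0)))

    def test_rows_sum_to_one(self):
        dag = sample_dag(5, edge_prob=0.5, rng=np.random.default_rng(5))
        model = sample_cpts(dag, strength=0.5, rng=np.random.default_rng(6))
        for node in dag.nodes:
            assert np.allclose(model.cpts[node].sum(axis=1), 1.0, atol=1e-12)

    def test_peak_mass_at_least_strength(self):
        dag = sample_dag(5, edge_prob=0.5, rng=np.random.default_rng(7))
        for strength in (1 / 3, 0.7, 0.95):
            model = sample_cpts(dag, strength=strength,
                                rng=np.random.default_rng(8))
            for node in dag.nodes:
                assert np.all(model.cpts[node].max(axis=1) >= strength - 1e-12)

    def test_invariants_enforced(self):
        dag = Dag(["a"])
        with pytest.raises(ValueError):
            GroundTruthModel(
                dag=dag, arity=3,
                cpts={"a": np.array([[0.5, 0.5, 0.5]])},
                emission_means={"a": np.array([0.0, 1.0, 2.0])},
                emission_sd=0.1,
            )
        with pytest.raises(ValueError):
            GroundTruthModel(
                dag=dag, arity=3,
                cpts={"a": np.full((1, 3), 1 / 3)},
                emission_means={"a": np.array([0.0, 2.0, 1.0])},
                emission_sd=0.1,
            )


class TestSimulate:
    def test_deterministic_chain(self):
        dag = Dag(["a", "b", "c"], {"b": {"a"}, "c": {"b"}})
        model = sample_cpts(dag, strength=1.0, rng=np.random.default_rng(9))
        disc, _ = simulate(model, 100, rng=np.random.default_rng(10))
        a, b = disc.row("a"), disc.row("b")
        # b must be a fixed function of a
        mapping = {}
        for x, y in zip(a, b):
            assert mapping.setdefault(x, y) == y

    def test_root_frequencies_converge(self):
        dag = Dag(["a"])
        model = sample_cpts(dag, strength=0.6, rng=np.random.default_rng(11))
        disc, _ = simulate(model, 10_000, rng=np.random.default_rng(12))
        freq = np.bincount(disc.row("a"), minlength=3) / 10_000
        p = model.cpts["a"][0]
        se = np.sqrt(p * (1 - p) / 10_000)
        assert np.all(np.abs(freq - p) <= 3 * se + 1e-9)

    def test_tiny_emission_noise_recoverable(self):
        # balanced state frequencies + vanishing emission noise: the
        # equal-frequency cuts land exactly between the emission clusters
        rng = np.random.default_rng(13)
        model = sample_cpts(Dag(["a", "b"]), emission_sd=1e-9,
                            rng=np.random.default_rng(14))
        m = 300
        states = np.vstack(
            [rng.permutation(np.repeat([0, 1, 2], m // 3)) for _ in range(2)]
        )
        values = np.vstack(
            [
                model.emission_means[g][states[i]]
                + model.emission_sd * rng.standard_normal(m)
                for i, g in enumerate(["a", "b"])
            ]
        )
        from bnexpand.io_formats import ExpressionMatrix

        expr = ExpressionMatrix(
            ["a", "b"], [f"s{j}" for j in range(m)], values
        )
        recovered = q3_discretize(expr)
        assert np.array_equal(recovered.states, states)

    def test_determinism(self):
        dag = sample_dag(4, edge_prob=0.4, rng=np.random.default_rng(16))
        model = sample_cpts(dag, rng=np.random.default_rng(17))
        d1, e1 = simulate(model, 50, rng=np.random.default_rng(18))
        d2, e2 = simulate(model, 50, rng=np.random.default_rng(18))
        assert np.array_equal(d1.states, d2.states)
        assert np.array_equal(e1.values, e2.values)

    def test_invalid_sample_count(self):
        dag = Dag(["a"])
        model = sample_cpts(dag, rng=np.random.default_rng(19))
        with pytest.raises(ValueError):
            simulate(model, 0)


class TestPlantRegulator:
    def _model(self, seed=20):
        dag = sample_dag(6, edge_prob=0.3, rng=np.random.default_rng(seed))
        return sample_cpts(dag, strength=0.9, rng=np.random.default_rng(seed + 1))

    def test_no_noise_candidates(self):
        augmented, core, candidates = plant_regulator(
            self._model(), n_targets=2, n_noise_candidates=0,
            rng=np.random.default_rng(22),
        )
        assert candidates == ["hidden00"]

    def test_hidden_children_count(self):
        augmented, core, candidates = plant_regulator(
            self._model(), n_targets=3, n_noise_candidates=2,
            rng=np.random.default_rng(23),
        )
        assert len(augmented.dag.children("hidden00")) == 3
        assert "hidden00" not in core.nodes

    def test_core_dag_unchanged(self):
        model = self._model()
        augmented, core, _ = plant_regulator(
            model, rng=np.random.default_rng(24)
        )
        assert core == model.dag

    def test_noise_independent_of_core(self):
        model = self._model()
        augmented, core, candidates = plant_regulator(
            model, n_targets=2, n_noise_candidates=3,
            rng=np.random.default_rng(25),
        )
        disc, _ = simulate(augmented, 10_000, rng=np.random.default_rng(26))
        noise = [c for c in candidates if c.startswith("noise")]
        rejections = 0
        tests = 0
        for g in noise:
            for h in core.nodes:
                table = np.zeros((3, 3), dtype=int)
                for x, y in zip(disc.row(g), disc.row(h)):
                    table[x, y] += 1
                table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
                if table.shape[0] < 2 or table.shape[1] < 2:
                    continue
                p = chi2_contingency(table).pvalue
                tests += 1
                if p < 0.01:
                    rejections += 1
        # nominal rate 1%; allow generous slack on ~18 tests
        assert rejections <= max(2, int(0.2 * tests))

    def test_too_many_targets_rejected(self):
        with pytest.raises(ValueError):
            plant_regulator(self._model(), n_targets=100)


class TestMakeMetadata:
    def _states(self):
        dag = Dag(["a", "b"])
        model = sample_cpts(dag, rng=np.random.default_rng(27))
        disc, _ = simulate(model, 120, rng=np.random.default_rng(28))
        return disc

    def test_exact_planting(self):
        disc = self._states()
        meta = make_metadata(
            disc, "a", "b", "biofilm", (2, 2), hit_rate=1.0,
            background_rate=0.0, rng=np.random.default_rng(29),
        )
        in_bin = {
            s for s, x, y in zip(disc.sample_ids, disc.row("a"), disc.row("b"))
            if (x, y) == (2, 2)
        }
        tagged = {m.sample_id for m in meta if "biofilm" in m.description}
        assert tagged == in_bin

    def test_null_rates_give_flat_pvalues(self):
        disc = self._states()
        pvals = []
        for seed in range(100):
            meta = make_metadata(
                disc, "a", "b", "biofilm", (2, 2), hit_rate=0.3,
                background_rate=0.3, rng=np.random.default_rng(500 + seed),
            )
            in_bin = np.array(
                [(x, y) == (2, 2) for x, y in zip(disc.row("a"), disc.row("b"))]
            )
            tagged = np.array(["biofilm" in m.description for m in meta])
            a = int((in_bin & tagged).sum())
            b = int((in_bin & ~tagged).sum())
            c = int((~in_bin & tagged).sum())
            d = int((~in_bin & ~tagged).sum())
            pvals.append(fisher_pvalue(a, b, c, d).one_sided)
        assert np.median(pvals) >= 0.1

    def test_every_sample_annotated(self):
        disc = self._states()
        meta = make_metadata(
            disc, "a", "b", "biofilm", (0, 0),
            rng=np.random.default_rng(30),
        )
        assert len(meta) == len(disc.sample_ids)
        assert all(m.title or m.description for m in meta)

    def test_bad_bin_rejected(self):
        disc = self._states()
        with pytest.raises(ValueError):
            make_metadata(disc, "a", "b", "x", (5, 0))
        with pytest.raises(ValueError):
            make_metadata(disc, "a", "b", "x", (0, 0), hit_rate=2.0)


def test_structure_recovery_end_to_end():
    """Skeleton F1 >= 0.8 on average when learning back an 8-node model."""
    f1s = []
    for seed in range(20):
        dag = sample_dag(8, edge_prob=0.3, rng=np.random.default_rng(7000 + seed))
        model = sample_cpts(dag, strength=0.9,
                            rng=np.random.default_rng(7100 + seed))
        disc, _ = simulate(model, 500, rng=np.random.default_rng(7200 + seed))
        cfg = SearchConfig(
            networks_per_run=40_000, restarts=5, rng_seed=seed
        )
        pool = multi_restart_search(disc, disc.gene_ids, cfg)
        truth = {frozenset(e) for e in dag.edges()}
        found = {frozenset(e) for e in pool.best.dag.edges()}
        tp = len(truth & found)
        prec = tp / len(found) if found else 1.0
        rec = tp / len(truth) if truth else 1.0
        f1s.append(0.0 if tp == 0 else 2 * prec * rec / (prec + rec))
    assert np.mean(f1s) >= 0.8, f1s
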