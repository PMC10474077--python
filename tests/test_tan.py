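"""TAN core: counts, conditional mutual information, structure, fitting, prediction."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import (
    all_spanning_trees,
    cmi_brute_force,
    posterior_brute_force,
    random_dataset,
    random_schema,
)
from fedbn.schema import DatasetSchema, StationDataset, VariableSpec
from fedbn.tan import (
    CPT,
    SufficientStatistics,
    TANModel,
    TANStructure,
    compute_sufficient_statistics,
    conditional_mutual_information,
    fit_parameters_bayes,
    learn_tan_structure,
    model_from_json,
    model_to_json,
    predict_class,
    predict_posterior,
    train_tan,
)


def _schema2(nc=2):
    return DatasetSchema((
        VariableSpec("C", tuple(f"c{i}" for i in range(nc)), "class"),
        VariableSpec("X", ("x0", "x1"), "feature"),
        VariableSpec("Y", ("y0", "y1"), "feature"),
    ))


class TestSufficientStatistics:
    def test_empty_dataset_all_zero(self, toy_schema):
        stats = compute_sufficient_statistics(StationDataset("S", toy_schema, []))
        assert stats.n == 0
        assert stats.class_counts.sum() == 0
        assert all(t.sum() == 0 for t in stats.pair_counts.values())

    def test_single_record_single_cells(self, toy_schema):
        ds = StationDataset("S", toy_schema, [("c1", "x0", "y2", "z1")])
        stats = compute_sufficient_statistics(ds)
        assert stats.n == 1
        for t in [stats.class_counts, *stats.single_counts.values(),
                  *stats.pair_counts.values()]:
            assert t.sum() == 1 and t.max() == 1

    def test_counts_match_brute_force_tally(self, toy_schema):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, toy_schema, 20)
        stats = compute_sufficient_statistics(ds)
        stats.validate()
        cmap = toy_schema.class_var.state_index()
        for (a, b), tensor in stats.pair_counts.items():
            ia, ib = toy_schema.index_of(a), toy_schema.index_of(b)
            amap = toy_schema[a].state_index()
            bmap = toy_schema[b].state_index()
            expect = np.zeros_like(tensor)
            for rec in ds.records:
                expect[cmap[rec[0]], amap[rec[ia]], bmap[rec[ib]]] += 1
            assert np.array_equal(tensor, expect)

    def test_payload_round_trip(self, toy_schema):
        ds = random_dataset(np.random.default_rng(5), toy_schema, 30)
        stats = compute_sufficient_statistics(ds)
        back = SufficientStatistics.from_payload(stats.to_payload(), toy_schema)
        assert back.n == stats.n
        for k in stats.pair_counts:
            assert np.array_equal(back.pair_counts[k], stats.pair_counts[k])


class TestCMI:
    def _stats_from_pair(self, tensor):
        """Build statistics for a 2-feature schema from a (C, a, b) count tensor."""
        tensor = np.asarray(tensor, dtype=np.int64)
        C = tensor.shape[0]
        schema = _schema2(C)
        recs = []
        for c, a, b in itertools.product(*map(range, tensor.shape)):
            recs += [(f"c{c}", f"x{a}", f"y{b}")] * int(tensor[c, a, b])
        return compute_sufficient_statistics(StationDataset("S", schema, recs))

    def test_conditional_independence_gives_zero(self):
        stats = self._stats_from_pair(np.full((2, 2, 2), 25))
        assert conditional_mutual_information(stats, "X", "Y") == 0.0

    def test_perfect_dependence_gives_ln2(self):
        # one class, X == Y with a uniform (50, 50) marginal
        stats = self._stats_from_pair([[[50, 0], [0, 50]]])
        got = conditional_mutual_information(stats, "X", "Y")
        assert got == pytest.approx(np.log(2), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_tensors(self, seed):
        rng = np.random.default_rng(seed)
        tensor = rng.integers(0, 9, size=(2, 2, 2))
        if tensor.sum() == 0:
            tensor[0, 0, 0] = 1
        stats = self._stats_from_pair(tensor)
        got = conditional_mutual_information(stats, "X", "Y")
        assert got == pytest.approx(cmi_brute_force(stats, "X", "Y"), abs=1e-12)

    def test_symmetry_and_nonnegativity(self, toy_schema):
        for seed in range(5):
            ds = random_dataset(np.random.default_rng(seed), toy_schema, 40)
            stats = compute_sufficient_statistics(ds)
            for a, b in itertools.combinations([v.name for v in toy_schema.feature_vars], 2):
                ab = conditional_mutual_information(stats, a, b)
                ba = conditional_mutual_information(stats, b, a)
                assert ab == pytest.approx(ba, abs=1e-12)
                assert ab >= 0.0

    def test_same_feature_is_error(self, toy_schema):
        stats = compute_sufficient_statistics(
            random_dataset(np.random.default_rng(0), toy_schema, 10)
        )
        with pytest.raises(ValueError, match="distinct"):
            conditional_mutual_information(stats, "X", "X")


class TestStructure:
    def test_two_features_forced_topology(self):
        ds = random_dataset(np.random.default_rng(1), _schema2(), 30)
        s = learn_tan_structure(compute_sufficient_statistics(ds))
        assert s.root == "X" and s.tree_edges == (("X", "Y"),)

    def test_fewer_than_two_features_is_error(self):
        schema = DatasetSchema((
            VariableSpec("C", ("c0", "c1"), "class"),
            VariableSpec("X", ("x0", "x1"), "feature"),
        ))
        ds = random_dataset(np.random.default_rng(0), schema, 10)
        with pytest.raises(ValueError, match="naive Bayes"):
            learn_tan_structure(compute_sufficient_statistics(ds))

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_search_on_four_features(self, seed):
        rng = np.random.default_rng(seed)
        schema = random_schema(rng, n_features=4, n_classes=2)
        ds = random_dataset(rng, schema, 60)
        stats = compute_sufficient_statistics(ds)
        feats = [v.name for v in schema.feature_vars]
        weights = {
            frozenset((a, b)): conditional_mutual_information(stats, a, b)
            for a, b in itertools.combinations(feats, 2)
        }
        trees = all_spanning_trees(feats)
        assert len(trees) == 16  # Cayley: 4^(4-2)
        best = max(trees, key=lambda t: sum(weights[e] for e in t))
        learned = learn_tan_structure(stats)
        learned_undirected = frozenset(frozenset(e) for e in learned.tree_edges)
        got_w = sum(weights[e] for e in learned_undirected)
        best_w = sum(weights[e] for e in best)
        assert got_w == pytest.approx(best_w, abs=1e-12)

    def test_equal_weights_give_star_on_first_feature(self):
        # one class, binary features, every joint combination once:
        # all pairwise CMIs are exactly zero, so the tie-break decides
        schema = DatasetSchema((
            VariableSpec("C", ("c",), "class"),
            VariableSpec("A", ("0", "1"), "feature"),
            VariableSpec("B", ("0", "1"), "feature"),
            VariableSpec("D", ("0", "1"), "feature"),
            VariableSpec("E", ("0", "1"), "feature"),
        ))
        recs = [("c", *bits) for bits in itertools.product("01", repeat=4)]
        stats = compute_sufficient_statistics(StationDataset("S", schema, recs))
        s1 = learn_tan_structure(stats)
        s2 = learn_tan_structure(stats)
        assert s1 == s2
        assert set(s1.tree_edges) == {("A", "B"), ("A", "D"), ("A", "E")}


class TestFitBayes:
    def _stats_with_class_counts(self, counts):
        schema = _schema2(len(counts))
        recs = []
        for c, k in enumerate(counts):
            recs += [(f"c{c}", "x0", "y0")] * k
        return compute_sufficient_statistics(StationDataset("S", schema, recs))

    def test_mle_limit(self):
        stats = self._stats_with_class_counts([3, 1])
        model = fit_parameters_bayes(stats, TANStructure("C", "X", (("X", "Y"),)), iss=0.0)
        assert model.class_prior.table == pytest.approx([0.75, 0.25])

    def test_posterior_mean_hand_value(self):
        # counts (2, 0), r = 2, q = 1, iss = 1 -> (2.5/3, 0.5/3)
        stats = self._stats_with_class_counts([2, 0])
        model = fit_parameters_bayes(stats, TANStructure("C", "X", (("X", "Y"),)), iss=1.0)
        assert model.class_prior.table == pytest.approx([2.5 / 3, 0.5 / 3], abs=1e-12)

    def test_prior_only_uniform(self):
        stats = SufficientStatistics.zeros(_schema2())
        model = fit_parameters_bayes(stats, TANStructure("C", "X", (("X", "Y"),)), iss=1.0)
        assert model.class_prior.table == pytest.approx([0.5, 0.5])

    def test_negative_iss_rejected(self):
        stats = self._stats_with_class_counts([3, 1])
        with pytest.raises(ValueError, match="non-negative"):
            fit_parameters_bayes(stats, TANStructure("C", "X", (("X", "Y"),)), iss=-1.0)

    def test_rows_normalized_and_positive(self, toy_schema):
        ds = random_dataset(np.random.default_rng(2), toy_schema, 50)
        model = train_tan(ds, iss=1.0)
        for cpt in [model.class_prior, *model.cpts.values()]:
            rows = cpt.table.reshape(-1, cpt.table.shape[-1])
            assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)
            assert (cpt.table > 0).all()

    def test_iss_limits(self, toy_schema):
        ds = random_dataset(np.random.default_rng(4), toy_schema, 80)
        stats = compute_sufficient_statistics(ds)
        structure = learn_tan_structure(stats)
        huge = fit_parameters_bayes(stats, structure, iss=1e9)
        for cpt in [huge.class_prior, *huge.cpts.values()]:
            r = cpt.table.shape[-1]
            assert np.allclose(cpt.table, 1.0 / r, atol=1e-5)
        tiny = fit_parameters_bayes(stats, structure, iss=1e-9)
        emp = stats.class_counts / stats.n
        assert np.allclose(tiny.class_prior.table, emp, atol=1e-9)


class TestPrediction:
    def _uniform_model(self):
        schema = _schema2()
        structure = TANStructure("C", "X", (("X", "Y"),))
        return TANModel(
            schema, structure,
            CPT("C", (), np.array([0.5, 0.5])),
            {
                "X": CPT("X", ("C",), np.full((2, 2), 0.5)),
                "Y": CPT("Y", ("C", "X"), np.full((2, 2, 2), 0.5)),
            },
        )

    def test_uniform_cpts_give_uniform_posterior(self):
        post = predict_posterior(self._uniform_model(), {"X": "x0", "Y": "y1"})
        assert post["c0"] == pytest.approx(0.5) and post["c1"] == pytest.approx(0.5)

    def test_point_mass_prior_dominates(self):
        model = self._uniform_model()
        model.class_prior = CPT("C", (), np.array([1.0, 0.0]))
        post = predict_posterior(model, {"X": "x1", "Y": "y0"})
        assert post["c0"] == pytest.approx(1.0)

    def test_tie_breaks_to_first_class_state(self):
        assert predict_class(self._uniform_model(), {"X": "x0", "Y": "y0"}) == "c0"

    def test_missing_feature_is_error(self):
        with pytest.raises(ValueError, match="missing feature"):
            predict_posterior(self._uniform_model(), {"X": "x0"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_joint_enumeration(self, seed, toy_schema):
        ds = random_dataset(np.random.default_rng(seed), toy_schema, 60)
        model = train_tan(ds, iss=1.0)
        feats = [v for v in toy_schema.feature_vars]
        for combo in itertools.product(*[v.states for v in feats]):
            record = {v.name: s for v, s in zip(feats, combo)}
            got = predict_posterior(model, record)
            want = posterior_brute_force(model, record)
            for c in got:
                assert got[c] == pytest.approx(want[c], abs=1e-10)
            states = model.schema.class_var.states
            first_best = next(s for s in states if want[s] == max(want.values()))
            assert predict_class(model, record) == first_best


class TestRecovery:
    def _strong_tan(self):
        """A TAN whose tree neighbors are strongly dependent (CMI well above 0.1)."""
        schema = DatasetSchema((
            VariableSpec("C", ("c0", "c1"), "class"),
            VariableSpec("A", ("0", "1"), "feature"),
            VariableSpec("B", ("0", "1"), "feature"),
            VariableSpec("D", ("0", "1"), "feature"),
        ))
        structure = TANStructure("C", "A", (("A", "B"), ("B", "D")))
        copy = np.array([[0.9, 0.1], [0.1, 0.9]])  # child copies parent w.p. 0.9
        prior = CPT("C", (), np.array([0.5, 0.5]))
        cpts = {
            "A": CPT("A", ("C",), np.array([[0.8, 0.2], [0.2, 0.8]])),
            "B": CPT("B", ("C", "A"), np.stack([copy, copy])),
            "D": CPT("D", ("C", "B"), np.stack([copy, copy])),
        }
        return TANModel(schema, structure, prior, cpts)

    def test_structure_and_parameters_recovered(self):
        from fedbn.scenario import generate_from_tan

        truth = self._strong_tan()
        true_edges = {frozenset(e) for e in truth.structure.tree_edges}
        ds = generate_from_tan(truth, 5000, seed=17)
        learned = train_tan(ds, iss=1.0)
        assert {frozenset(e) for e in learned.structure.tree_edges} == true_edges
        for name, cpt in truth.cpts.items():
            err = np.abs(learned.cpts[name].table - cpt.table).max()
            assert err <= 0.05


def test_model_json_round_trip(toy_schema):
    ds = random_dataset(np.random.default_rng(9), toy_schema, 40)
    model = train_tan(ds, iss=2.0)
    back = model_from_json(model_to_json(model))
    assert back.structure == model.structure
    assert back.iss == model.iss
    assert np.allclose(back.class_prior.table, model.class_prior.table)
    for name in model.cpts:
        assert np.allclose(back.cpts[name].table, model.cpts[name].table)
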