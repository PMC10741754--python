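import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from uskg import (EmbeddingModel, SimpleKG, TrainConfig, Triple,
                  complete_entity, gaussian_proximity, kgcm_score,
                  project_onto_hyperplane, train, transh_score)
from uskg.synthetic import generate_planted_kg

VEC = arrays(np.float64, 4, elements=st.floats(-2, 2))


def toy_model(entity_vectors, relation, d_r, w_r, sigma=1.0):
    names = sorted(entity_vectors)
    return EmbeddingModel(
        names, [relation],
        np.array([entity_vectors[n] for n in names], dtype=float),
        np.array([d_r], dtype=float), np.array([w_r], dtype=float),
        sigma=sigma)


class TestProjection:
    def test_vector_in_plane_is_unchanged(self):
        e = np.array([0.0, 2.0, 1.0])
        w = np.array([1.0, 0.0, 0.0])
        assert np.allclose(project_onto_hyperplane(e, w), e)

    def test_normal_direction_collapses_to_zero(self):
        w = np.array([0.0, 1.0])
        assert np.allclose(project_onto_hyperplane(w, w), 0.0)

    def test_analytic_example(self):
        got = project_onto_hyperplane(np.array([1.0, 1.0]),
                                      np.array([1.0, 0.0]))
        assert np.allclose(got, [0.0, 1.0])

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            project_onto_hyperplane(np.ones(2), np.array([1.0, 1.0]))

    @given(e=VEC, raw=VEC)
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_orthogonal(self, e, raw):
        if np.linalg.norm(raw) < 1e-6:
            return
        w = raw / np.linalg.norm(raw)
        p = project_onto_hyperplane(e, w)
        assert abs(float(np.dot(p, w))) < 1e-9
        assert np.allclose(project_onto_hyperplane(p, w), p, atol=1e-9)


class TestScores:
    def test_perfect_translation_scores_zero(self):
        w = np.array([0.0, 1.0])
        d = np.array([0.5, 0.0])
        model = toy_model({"h": [0.2, 0.7], "t": [0.7, -0.3]}, "r", d, w)
        assert transh_score(("h", "r", "t"), model) == pytest.approx(0.0)

    def test_hand_computed_two_dimensional_instance(self):
        model = toy_model({"h": [1.0, 0.0], "t": [0.0, 1.0]}, "r",
                          [0.0, 0.0], [0.0, 1.0])
        assert transh_score(("h", "r", "t"), model) == pytest.approx(1.0)

    def test_out_of_vocabulary_names_offender(self):
        model = toy_model({"h": [1.0, 0.0], "t": [0.0, 1.0]}, "r",
                          [0.0, 0.0], [0.0, 1.0])
        with pytest.raises(KeyError, match="ghost"):
            transh_score(("ghost", "r", "t"), model)
        with pytest.raises(KeyError, match="nope"):
            kgcm_score(("h", "nope", "t"), model)

    @given(data=st.data())
    @settings(max_examples=200, derandomize=True)
    def test_matches_componentwise_arithmetic_oracle(self, data):
        dim = data.draw(st.integers(2, 5))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        ev = {"h": rng.normal(size=dim), "t": rng.normal(size=dim)}
        d = rng.normal(size=dim)
        w = rng.normal(size=dim)
        w /= np.linalg.norm(w)
        model = toy_model(ev, "r", d, w, sigma=0.8)
        # plain-python recomputation, no linear-algebra helpers
        def proj(v):
            dot = sum(w[k] * v[k] for k in range(dim))
            return [v[k] - dot * w[k] for k in range(dim)]
        hp, tp = proj(ev["h"]), proj(ev["t"])
        expected = sum((hp[k] + d[k] - tp[k]) ** 2 for k in range(dim))
        assert transh_score(("h", "r", "t"), model) == \
            pytest.approx(expected, abs=1e-9)
        sq = sum((ev["h"][k] - ev["t"][k]) ** 2 for k in range(dim))
        kernel = math.exp(-sq / (2 * 0.8 ** 2))
        assert kgcm_score(("h", "r", "t"), model) == \
            pytest.approx(expected * kernel, abs=1e-9)
        assert kgcm_score(("h", "r", "t"), model,
                          kernel_direction="divide") == \
            pytest.approx(expected / kernel, rel=1e-9)


class TestKernel:
    def test_zero_distance_is_one(self):
        v = np.array([0.3, 0.4])
        assert gaussian_proximity(v, v, 1.0) == pytest.approx(1.0)

    def test_analytic_value_at_two_sigma_squared(self):
        # squared distance 2*sigma^2 -> exp(-1)
        sigma = 0.7
        e_i = np.zeros(3)
        e_j = np.array([math.sqrt(2) * sigma, 0.0, 0.0])
        assert gaussian_proximity(e_i, e_j, sigma) == \
            pytest.approx(math.exp(-1), abs=1e-12)

    def test_monotone_decreasing_in_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(size=3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            d1, d2 = sorted(rng.uniform(0.1, 3.0, size=2))
            k1 = gaussian_proximity(a, a + d1 * direction, 1.0)
            k2 = gaussian_proximity(a, a + d2 * direction, 1.0)
            assert k1 >= k2
            assert 0.0 < k2 <= 1.0

    def test_symmetry(self):
        a, b = np.array([1.0, 2.0]), np.array([-0.5, 0.3])
        assert gaussian_proximity(a, b, 0.9) == \
            pytest.approx(gaussian_proximity(b, a, 0.9))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_proximity(np.zeros(2), np.ones(2), 0.0)


class TestKgcmScore:
    def test_zero_translation_residual_annihilates(self):
        w = np.array([0.0, 1.0])
        model = toy_model({"h": [0.2, 0.7], "t": [0.7, -0.3]}, "r",
                          [0.5, 0.0], w)
        assert kgcm_score(("h", "r", "t"), model) == pytest.approx(0.0)

    def test_identical_entities_reduce_to_transh(self):
        model = toy_model({"h": [0.5, 0.2], "t": [0.5, 0.2]}, "r",
                          [0.3, 0.0], [0.0, 1.0])
        assert kgcm_score(("h", "r", "t"), model) == \
            pytest.approx(transh_score(("h", "r", "t"), model))


class TestTraining:
    def _triples(self):
        kg = generate_planted_kg(n_entities=20, n_relations=2, dim=6,
                                 noise=0.0, seed=5, n_triples=60,
                                 n_queries=4)
        return kg

    def test_zero_epochs_returns_seeded_initialization(self):
        kg = self._triples()
        a = train(kg.triples, TrainConfig(seed=9, epochs=0), dim=6)
        b = train(kg.triples, TrainConfig(seed=9, epochs=0), dim=6)
        assert np.array_equal(a.entity_matrix, b.entity_matrix)
        assert a.loss_trace == []

    def test_same_seed_reproduces_loss_trace(self):
        kg = self._triples()
        a = train(kg.triples, TrainConfig(seed=2, epochs=5), dim=6)
        b = train(kg.triples, TrainConfig(seed=2, epochs=5), dim=6)
        assert a.loss_trace == b.loss_trace
        assert np.array_equal(a.entity_matrix, b.entity_matrix)

    def test_training_separates_facts_from_corruptions(self):
        kg = self._triples()
        model = train(kg.triples, TrainConfig(seed=0, epochs=60), dim=8)
        rng = np.random.default_rng(1)
        pos = [transh_score(t, model) for t in kg.triples[:40]]
        ents = model.entities
        neg = [transh_score((ents[rng.integers(len(ents))], t.relation,
                             t.tail), model) for t in kg.triples[:40]]
        assert np.mean(pos) < np.mean(neg)

    def test_unit_normals_and_entity_ball_maintained(self):
        kg = self._triples()
        model = train(kg.triples, TrainConfig(seed=0, epochs=10), dim=6)
        norms = np.linalg.norm(model.normal_matrix, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)
        assert (np.linalg.norm(model.entity_matrix, axis=1)
                <= 1.0 + 1e-9).all()

    def test_placeholder_and_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig())
        with pytest.raises(ValueError):
            train([Triple("@", "r", "t")], TrainConfig())

    def test_checkpoint_round_trip(self, tmp_path):
        kg = self._triples()
        model = train(kg.triples, TrainConfig(seed=0, epochs=2), dim=6)
        model.save(tmp_path / "ckpt")
        back = EmbeddingModel.load(tmp_path / "ckpt")
        assert back.entities == model.entities
        assert np.allclose(back.entity_matrix, model.entity_matrix)
        assert back.sigma == model.sigma


class TestCompletion:
    def test_no_placeholders_is_identity(self):
        kg = generate_planted_kg(n_entities=20, n_relations=2, dim=6,
                                 noise=0.0, seed=5, n_triples=40,
                                 n_queries=2)
        skg = SimpleKG(kg.triples[:10])
        out = complete_entity(skg, kg.model())
        assert [t.spo for t in out] == [t.spo for t in skg]

    def test_exhaustive_argmin_oracle_agreement(self):
        kg = generate_planted_kg(n_entities=24, n_relations=3, dim=7,
                                 noise=0.02, seed=8, n_triples=60,
                                 n_queries=6)
        model = kg.model()
        out = complete_entity(kg.query_skg(), model, candidate_policy="all")
        for filled, query in zip(out.triples, kg.queries):
            scores = {
                e: kgcm_score((e, query.relation, query.tail), model,
                              kernel_direction="divide")
                for e in model.entities if e != query.tail}
            best = min(sorted(scores), key=lambda e: scores[e])
            assert filled.head == best

    def test_unknown_relation_leaves_placeholder(self):
        kg = generate_planted_kg(n_entities=20, n_relations=2, dim=6,
                                 noise=0.0, seed=5, n_triples=40,
                                 n_queries=2)
        skg = SimpleKG([Triple("@", "unseen-relation", kg.queries[0].tail)])
        out = complete_entity(skg, kg.model())
        assert out.triples[0].is_placeholder

    def test_report_policy_prefers_earlier_mentions(self):
        # two candidate heads fit equally; the one mentioned earlier wins
        w = np.array([0.0, 0.0, 1.0])
        d = np.array([0.3, 0.0, 0.0])
        ev = {"a": [0.1, 0.2, 0.0], "b": [0.1, 0.2, 0.5],
              "t": [0.4, 0.2, 0.0], "x": [0.9, -0.7, 0.0]}
        model = toy_model(ev, "r", d, w)
        skg = SimpleKG([
            Triple("a", "r", "x", "rep", 0),
            Triple("b", "r", "x", "rep", 1),
            Triple("@", "r", "t", "rep", 2),
        ])
        out = complete_entity(skg, model, scorer="transh")
        assert out.triples[2].head == "a"
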