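import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedproto.fewshot import (
    SamplingError,
    build_backbone,
    classify_queries,
    compute_prototypes,
    episode_loss,
    episode_loss_grad,
    sample_episode,
)
from fedproto.synthetic import SynthConfig, generate_balanced_index


@pytest.fixture(scope="module")
def pool():
    cfg = SynthConfig(image_size=12, depth_range=(3, 5), planes=("axial",), seed=3)
    return generate_balanced_index([0, 1, 3, 4], 16, cfg)


class TestBuildBackbone:
    def test_same_seed_gives_identical_weights(self):
        a = build_backbone("tiny3d", 32, seed=9)
        b = build_backbone("tiny3d", 32, seed=9)
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_embedding_shape_contract(self):
        bb = build_backbone("tiny3d", 64, seed=0)
        x = np.zeros((4, 3, 15, 32, 32), dtype=np.float32)
        assert bb.embed(x).shape == (4, 64)

    def test_deeper_resnet_has_more_parameters(self):
        n10 = build_backbone("resnet3d-10", 16, seed=0).n_parameters()
        n50 = build_backbone("resnet3d-50", 16, seed=0).n_parameters()
        assert n50 > n10

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_backbone("vgg", 8, seed=0)

    def test_shape_mismatch_on_weight_load(self):
        small = build_backbone("tiny3d", 8, seed=0)
        with pytest.raises(ValueError, match="shape mismatch"):
            build_backbone("tiny3d", 16, seed=0, init_weights=small.weights)


class TestSampleEpisode:
    def test_three_way_five_shot_counts(self, pool, rng):
        ep = sample_episode(pool, 3, 5, 10, rng)
        assert len(ep.support_items) == 15
        assert len(ep.query_items) == 30
        for label in range(3):
            assert (ep.support_labels == label).sum() == 5
            assert (ep.query_labels == label).sum() == 10

    def test_two_way_eight_shot_validation_geometry(self, pool, rng):
        ep = sample_episode(pool, 2, 8, 0, rng)  # empty query allowed at sampling
        assert len(ep.support_items) == 16

    def test_support_query_disjoint_and_mapped(self, pool, rng):
        ep = sample_episode(pool, 3, 2, 3, rng)
        support = {r.exam_id for r in ep.support_items}
        query = {r.exam_id for r in ep.query_items}
        assert not support & query
        assert ep.class_map == sorted(ep.class_map)
        for rec, lab in zip(ep.support_items, ep.support_labels):
            assert rec.class_id == ep.class_map[lab]

    def test_insufficient_class_raises_with_name(self, pool, rng):
        with pytest.raises(SamplingError):
            sample_episode(pool, 4, 5, 12, rng)  # needs 17 > 16 per class

    def test_episode_json_dump_round_trips(self, pool, rng):
        import json

        ep = sample_episode(pool, 2, 2, 2, rng)
        doc = json.loads(ep.to_json())
        assert doc["n_way"] == 2 and len(doc["support"]) == 4


class TestPrototypes:
    def test_single_embedding_is_its_own_prototype(self):
        protos = compute_prototypes(np.array([[1.0, 2.0], [5.0, 6.0]]), [0, 1])
        assert np.allclose(protos.vectors, [[1, 2], [5, 6]])

    def test_mean_of_two(self):
        protos = compute_prototypes(np.array([[1.0, 1.0], [3.0, 3.0]]), [0, 0])
        assert np.allclose(protos.vectors, [[2.0, 2.0]])

    def test_permutation_invariant_by_exhaustion(self):
        emb = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0], [0.0, 5.0]])
        labels = np.array([0, 0, 1, 1])
        reference = compute_prototypes(emb, labels).vectors
        for perm in itertools.permutations(range(4)):
            perm = list(perm)
            got = compute_prototypes(emb[perm], labels[perm]).vectors
            assert np.allclose(got, reference)

    def test_matches_groupwise_mean_oracle_on_random_supports(self, rng):
        for _ in range(10):
            n_way = int(rng.integers(2, 5))
            k_shot = int(rng.integers(1, 4))
            emb = rng.normal(size=(n_way * k_shot, 5))
            labels = np.repeat(np.arange(n_way), k_shot)
            shuffle = rng.permutation(len(labels))
            protos = compute_prototypes(emb[shuffle], labels[shuffle])
            oracle = np.stack([emb[labels == k].mean(axis=0) for k in range(n_way)])
            assert np.allclose(protos.vectors, oracle)


class TestClassifyQueries:
    def test_query_on_prototype_is_classified_there(self):
        protos = compute_prototypes(np.array([[0.0, 0.0], [4.0, 4.0]]), [0, 1])
        logits, preds, _ = classify_queries(protos, np.array([[0.0, 0.0]]))
        assert preds[0] == 0
        assert logits[0, 0] == 0.0

    def test_hand_evaluated_softmax(self):
        """Prototypes (0,0) and (10,0), query (1,0): squared distances 1 and
        81, so p(class 0) = e^-1 / (e^-1 + e^-81)."""
        protos = compute_prototypes(np.array([[0.0, 0.0], [10.0, 0.0]]), [0, 1])
        logits, preds, probs = classify_queries(protos, np.array([[1.0, 0.0]]))
        assert np.allclose(logits[0], [-1.0, -81.0])
        assert preds[0] == 0
        expected = np.exp(-1) / (np.exp(-1) + np.exp(-81))
        assert probs[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_equidistant_tie_breaks_to_lowest_class(self):
        protos = compute_prototypes(np.array([[-1.0, 0.0], [1.0, 0.0]]), [0, 1])
        _, preds, _ = classify_queries(protos, np.array([[0.0, 0.0]]))
        assert preds[0] == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), shift=st.floats(-50, 50))
    def test_translation_invariance(self, seed, shift):
        r = np.random.default_rng(seed)
        emb = r.normal(size=(6, 4))
        protos = compute_prototypes(emb, [0, 0, 1, 1, 2, 2])
        q = r.normal(size=(3, 4))
        _, preds, probs = classify_queries(protos, q)
        moved = compute_prototypes(emb + shift, [0, 0, 1, 1, 2, 2])
        _, preds2, probs2 = classify_queries(moved, q + shift)
        assert np.array_equal(preds, preds2)
        assert np.allclose(probs, probs2, atol=1e-8)

    def test_probabilities_sum_to_one(self, rng):
        protos = compute_prototypes(rng.normal(size=(4, 8)), [0, 1, 2, 3])
        _, _, probs = classify_queries(protos, rng.normal(size=(10, 8)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        protos = compute_prototypes(np.zeros((2, 3)), [0, 1])
        with pytest.raises(ValueError):
            classify_queries(protos, np.zeros((1, 4)))


class TestEpisodeLoss:
    def test_confident_correct_is_near_zero(self):
        assert episode_loss(np.array([[0.0, -1e4]]), [0]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_give_ln2(self):
        assert episode_loss(np.array([[1.0, 1.0]]), [1]) == pytest.approx(np.log(2))

    def test_batch_loss_is_mean_of_per_query_losses(self, rng):
        logits = rng.normal(size=(7, 3))
        labels = rng.integers(0, 3, size=7)
        per_query = [episode_loss(logits[i : i + 1], labels[i : i + 1]) for i in range(7)]
        assert episode_loss(logits, labels) == pytest.approx(np.mean(per_query))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            episode_loss(np.zeros((1, 2)), [2])

    def test_loss_grad_rows_sum_to_zero(self, rng):
        g = episode_loss_grad(rng.normal(size=(5, 3)), rng.integers(0, 3, size=5))
        assert np.allclose(g.sum(axis=1), 0.0, atol=1e-12)


def test_support_identical_to_query_yields_perfect_one_shot_accuracy(rng):
    emb = rng.normal(size=(3, 6))
    protos = compute_prototypes(emb, [0, 1, 2])
    _, preds, _ = classify_queries(protos, emb)
    assert np.array_equal(preds, [0, 1, 2])
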