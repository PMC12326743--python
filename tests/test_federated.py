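import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedproto.exam_io import DatasetIndex, ExamRecord
from fedproto.federated import (
    AggregationError,
    FedConfig,
    StratificationError,
    fedavg,
    partition_clients,
    run_federated,
)
from fedproto.preprocess import AugmentConfig
from fedproto.synthetic import SynthConfig, generate_balanced_index
from fedproto.training import EpisodeSpec, TrainConfig


@pytest.fixture(scope="module")
def pool():
    cfg = SynthConfig(image_size=12, depth_range=(3, 5), planes=("axial",), seed=21)
    return generate_balanced_index([0, 1, 3], 10, cfg)


class TestPartitionClients:
    def test_disjoint_exhaustive_split(self, pool, rng):
        shards = partition_clients(pool, 2, rng)
        ids = [frozenset(r.exam_id for r in s.records) for s in shards]
        assert not ids[0] & ids[1]
        assert ids[0] | ids[1] == {r.exam_id for r in pool.records}
        assert len(shards[0]) == len(shards[1]) == 15

    def test_stratified_by_class(self, pool, rng):
        shards = partition_clients(pool, 2, rng)
        for s in shards:
            assert s.class_counts == {0: 5, 1: 5, 3: 5}

    def test_same_seed_same_partition(self, pool):
        a = partition_clients(pool, 2, np.random.default_rng(3))
        b = partition_clients(pool, 2, np.random.default_rng(3))
        for sa, sb in zip(a, b):
            assert [r.exam_id for r in sa.records] == [r.exam_id for r in sb.records]

    def test_class_smaller_than_client_count_rejected(self, rng):
        cfg = SynthConfig(image_size=8, depth_range=(3, 4), planes=("axial",), seed=1)
        tiny = generate_balanced_index([0], 1, cfg)
        with pytest.raises(StratificationError):
            partition_clients(tiny, 2, rng)


class TestFedavg:
    def test_identical_clients_are_a_fixed_point(self, rng):
        w = {"a": rng.normal(size=(3, 2)), "b": rng.normal(size=(4,))}
        out = fedavg([w, {k: v.copy() for k, v in w.items()}], [10, 30])
        for k in w:
            assert np.allclose(out[k], w[k])

    def test_scalar_convex_combination(self):
        out = fedavg([{"w": np.array(0.0)}, {"w": np.array(4.0)}], [1, 3])
        assert out["w"] == pytest.approx(3.0)

    def test_equal_sizes_match_elementwise_mean_oracle(self, rng):
        clients = [
            {"w": rng.normal(size=(5, 4)), "b": rng.normal(size=(7,))}
            for _ in range(3)
        ]
        out = fedavg(clients, [4, 4, 4])
        for k in ("w", "b"):
            oracle = np.mean([c[k] for c in clients], axis=0)
            assert np.allclose(out[k], oracle)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n_clients=st.integers(2, 4))
    def test_weighted_mean_oracle_and_permutation_invariance(self, seed, n_clients):
        r = np.random.default_rng(seed)
        sizes = r.integers(1, 20, size=n_clients).tolist()
        clients = [{"p": r.normal(size=(3, 3))} for _ in range(n_clients)]
        out = fedavg(clients, sizes)
        oracle = sum(s * c["p"] for s, c in zip(sizes, clients)) / sum(sizes)
        assert np.allclose(out["p"], oracle)
        perm = r.permutation(n_clients)
        out2 = fedavg([clients[i] for i in perm], [sizes[i] for i in perm])
        assert np.allclose(out["p"], out2["p"])
        # envelope: every coordinate within client min/max
        stack = np.stack([c["p"] for c in clients])
        assert (out["p"] >= stack.min(axis=0) - 1e-12).all()
        assert (out["p"] <= stack.max(axis=0) + 1e-12).all()

    def test_homogeneous_of_degree_one(self, rng):
        clients = [{"p": rng.normal(size=(2, 2))} for _ in range(2)]
        out = fedavg(clients, [1, 2])
        scaled = fedavg([{"p": 3.0 * c["p"]} for c in clients], [1, 2])
        assert np.allclose(scaled["p"], 3.0 * out["p"])

    def test_name_and_shape_mismatches_rejected(self, rng):
        a = {"p": np.zeros((2, 2))}
        with pytest.raises(AggregationError):
            fedavg([a, {"q": np.zeros((2, 2))}], [1, 1])
        with pytest.raises(AggregationError):
            fedavg([a, {"p": np.zeros((3, 2))}], [1, 1])
        with pytest.raises(AggregationError):
            fedavg([a, a], [1, 0])


@pytest.fixture(scope="module")
def fed_setup():
    cfg = SynthConfig(image_size=12, depth_range=(3, 5), planes=("axial",), seed=22)
    train = generate_balanced_index([1, 2, 4], 8, cfg, stream=1)
    val = generate_balanced_index([1, 2, 4], 6, cfg, stream=2)
    ft = generate_balanced_index([0, 3], 8, cfg, stream=3)
    inner = TrainConfig(
        epochs=1, tasks_per_epoch_train=2, tasks_per_epoch_val=2,
        train_spec=EpisodeSpec(2, 2), val_spec=EpisodeSpec(2, 2),
        n_query=2, val_n_query=2, seed=9, plane="axial", target_depth=5,
        augment=AugmentConfig(out_size=12),
    )
    # micro shards cannot host the default 2-way 5-shot fine-tune
    # validation, so the stage-2 budget is stated explicitly
    return train, val, ft, FedConfig(
        n_clients=2, rounds=1, partition_seed=4, train=inner,
        finetune_train=inner,
    )


class TestRunFederated:

    def test_deterministic_global_checkpoint(self, fed_setup):
        train, val, ft, cfg = fed_setup
        a = run_federated(train, val, ft, cfg, embed_dim=8)
        b = run_federated(train, val, ft, cfg, embed_dim=8)
        for k in a.global_checkpoint.weights:
            assert np.array_equal(
                a.global_checkpoint.weights[k], b.global_checkpoint.weights[k]
            )

    def test_result_exposes_no_exam_data(self, fed_setup):
        """Privacy audit: nothing reachable from the server-side result holds
        exam records or volume arrays."""
        train, val, ft, cfg = fed_setup
        result = run_federated(train, val, ft, cfg, embed_dim=8)

        seen = set()

        def walk(obj, depth=0):
            if id(obj) in seen or depth > 6:
                return
            seen.add(id(obj))
            assert not isinstance(obj, (ExamRecord, DatasetIndex))
            if isinstance(obj, dict):
                for v in obj.values():
                    walk(v, depth + 1)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v, depth + 1)
            elif hasattr(obj, "__dict__"):
                for v in vars(obj).values():
                    walk(v, depth + 1)

        walk(result)

    def test_histories_cover_both_clients_and_stages(self, fed_setup):
        train, val, ft, cfg = fed_setup
        result = run_federated(train, val, ft, cfg, embed_dim=8)
        stages = {(h["client"], h["stage"]) for h in result.client_histories}
        assert stages == {(0, "train"), (0, "finetune"), (1, "train"), (1, "finetune")}

    def test_best_client_rule(self, fed_setup):
        import dataclasses

        train, val, ft, cfg = fed_setup
        cfg2 = dataclasses.replace(cfg, aggregate_after_finetune=False)
        result = run_federated(train, val, ft, cfg2, embed_dim=8)
        assert result.final_model_rule == "best_client"
        assert result.global_checkpoint.val_accuracy == max(result.client_val_accuracies)


def test_fed_config_validation():
    with pytest.raises(ValueError):
        FedConfig(n_clients=1)
    with pytest.raises(ValueError):
        FedConfig(rounds=0)
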