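import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_affinity_pair
from eemap.affinities import build_affinity_pair
from eemap.containers import ExpressionMatrix
from eemap.ee import ee_objective
from eemap.evaluation import knn_cv_error
from eemap.network import (
    TrainConfig,
    ee_parameter_gradient,
    forward_map,
    init_network,
)
from eemap.stochastic import (
    BatchPartition,
    averaged_gradient,
    batch_affinities,
    partition_batches,
    train_stochastic,
    update_online,
)
from eemap.synthetic import generate_gaussian_clusters


class TestPartition:
    def test_even_split(self):
        p = partition_batches(10, 5, seed=0)
        assert p.n_batches == 2
        assert sorted(np.concatenate(p.batches).tolist()) == list(range(10))
        assert all(len(b) == 5 for b in p.batches)

    def test_remainder_balanced(self):
        # ceil(12/5)=3 batches; balance forces sizes 4,4,4
        p = partition_batches(12, 5, seed=1)
        assert [len(b) for b in p.batches] == [4, 4, 4]

    def test_deterministic_per_seed(self):
        a = partition_batches(23, 7, seed=3)
        b = partition_batches(23, 7, seed=3)
        for x, y in zip(a.batches, b.batches):
            np.testing.assert_array_equal(x, y)
        c = partition_batches(23, 7, seed=4)
        assert any(
            not np.array_equal(x, y) for x, y in zip(a.batches, c.batches)
        )

    @pytest.mark.parametrize("n,bs,seed", [(17, 4, 0), (50, 9, 2), (8, 2, 7), (100, 33, 5)])
    def test_disjoint_cover_sweep(self, n, bs, seed):
        p = partition_batches(n, bs, seed)
        allidx = np.concatenate(p.batches)
        assert len(allidx) == n
        assert len(np.unique(allidx)) == n
        sizes = [len(b) for b in p.batches]
        assert max(sizes) - min(sizes) <= 1
        assert len(sizes) == -(-n // bs)

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError):
            partition_batches(10, 1, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        n=st.integers(min_value=4, max_value=300),
        bs=st.integers(min_value=2, max_value=300),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_partition_properties(self, n, bs, seed):
        """Disjointness, coverage, batch count and size balance hold for any
        valid (N, batch_size, seed)."""
        bs = min(bs, n)
        p = partition_batches(n, bs, seed)
        allidx = np.concatenate(p.batches)
        assert len(allidx) == n and len(np.unique(allidx)) == n
        if bs == 2 and n % 2 == 1:
            # an odd cell count cannot be covered by pairs alone; one batch
            # of 3 replaces the degenerate singleton
            assert p.n_batches == n // 2
        else:
            assert p.n_batches == -(-n // bs)
        sizes = [len(b) for b in p.batches]
        assert max(sizes) - min(sizes) <= 1 and min(sizes) >= 2


class TestBatchAffinities:
    def test_single_batch_equals_full_build(self, rng):
        m = ExpressionMatrix(rng.normal(size=(12, 4)))
        p = partition_batches(12, 12, seed=0)
        p = batch_affinities(m, p, "entropic", 5.0, 1.0)
        full = build_affinity_pair(m, "entropic", 5.0, 1.0)
        np.testing.assert_array_equal(p.per_batch_affinities[0].wplus, full.wplus)
        np.testing.assert_array_equal(p.per_batch_affinities[0].wminus, full.wminus)

    def test_per_batch_invariants(self, rng):
        m = ExpressionMatrix(rng.normal(size=(20, 3)))
        p = batch_affinities(m, partition_batches(20, 7, seed=1), "gaussian", 1.0)
        for a in p.per_batch_affinities:
            assert np.array_equal(a.wplus, a.wplus.T)
            assert np.all(np.diagonal(a.wplus) == 0)
            assert np.all(np.diagonal(a.wminus) == 0)

    def test_duplicated_points_gaussian(self):
        m = ExpressionMatrix(np.ones((6, 3)))
        p = batch_affinities(
            m, partition_batches(6, 3, seed=0), "gaussian", 1.0, normalize="none"
        )
        for a in p.per_batch_affinities:
            off = a.wplus[~np.eye(a.n, dtype=bool)]
            assert np.all(off == 1.0)


class TestStochasticGradient:
    def test_single_batch_gradient_bitwise_equals_full(self, rng):
        """With one batch the averaged mini-batch gradient reduces exactly —
        bitwise — to the full-batch gradient at identical parameters."""
        m = ExpressionMatrix(rng.normal(size=(10, 4)))
        p = batch_affinities(m, partition_batches(10, 10, seed=0), "entropic", 4.0)
        net = init_network(4, 2, (5,), seed=1)
        grads_so, _ = averaged_gradient(m, p, net)
        gw, gb, _ = ee_parameter_gradient(
            net, m.values, p.per_batch_affinities[0]
        )
        for g_so, g_full in zip(grads_so, gw + gb):
            np.testing.assert_array_equal(g_so, g_full)

    def test_two_batch_average_matches_per_batch_oracle(self, rng):
        m = ExpressionMatrix(rng.normal(size=(8, 3)))
        p = batch_affinities(m, partition_batches(8, 4, seed=2), "gaussian", 1.0)
        net = init_network(3, 2, (4,), seed=0)
        grads, _ = averaged_gradient(m, p, net)
        # independent recomputation, batch by batch
        per_batch = []
        for b, aff in zip(p.batches, p.per_batch_affinities):
            gw, gb, _ = ee_parameter_gradient(net, m.values[b], aff)
            per_batch.append(gw + gb)
        for i, g in enumerate(grads):
            expected = (per_batch[0][i] + per_batch[1][i]) / 2.0
            np.testing.assert_allclose(g, expected, rtol=1e-15)

    def test_separated_clusters_resolved(self):
        m, labels = generate_gaussian_clusters(2, 30, 10, separation=40.0, seed=3)
        p = batch_affinities(m, partition_batches(60, 30, seed=0), "entropic", 10.0)
        net = init_network(10, 2, (32, 16), seed=1)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=200, tol=0.0, seed=0)
        _, emb, _ = train_stochastic(m, p, net, cfg)
        assert knn_cv_error(emb, labels, k=1, n_folds=5, seed=0) == 0.0

    def test_cycling_mode_runs(self, rng):
        m = ExpressionMatrix(rng.normal(size=(12, 3)))
        p = batch_affinities(m, partition_batches(12, 6, seed=0), "gaussian", 1.0)
        net = init_network(3, 2, (4,), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, tol=0.0)
        _, emb, trace = train_stochastic(m, p, net, cfg, cycle_batches=True)
        assert emb.coords.shape == (12, 2)
        assert len(trace) == 5

    def test_requires_offline_affinities(self, rng):
        m = ExpressionMatrix(rng.normal(size=(8, 3)))
        p = partition_batches(8, 4, seed=0)
        net = init_network(3, 2, (4,), seed=0)
        with pytest.raises(ValueError, match="offline"):
            train_stochastic(m, p, net, TrainConfig())


class TestOnlineUpdate:
    def test_zero_epochs_is_identity(self, rng):
        net = init_network(4, 2, (5,), seed=0)
        before = [p.copy() for p in net.parameters()]
        new = ExpressionMatrix(rng.normal(size=(6, 4)))
        net = update_online(net, new, TrainConfig(), epochs=0)
        for b, p in zip(before, net.parameters()):
            np.testing.assert_array_equal(b, p)

    def test_descent_on_revisited_batch(self, rng):
        """One small online step on a batch the model already saw must not
        increase that batch's objective."""
        m = ExpressionMatrix(rng.normal(size=(10, 4)))
        aff = build_affinity_pair(m, "gaussian", 1.0)
        net = init_network(4, 2, (6,), seed=2)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=50, tol=0.0, seed=0)
        from eemap.network import train_full_batch
        net, _, _ = train_full_batch(m, aff, net, cfg)
        before = ee_objective(forward_map(net, m).coords, aff)
        small = TrainConfig(learning_rate=1e-5, max_epochs=1, tol=0.0,
                            optimizer="sgd", seed=0)
        net = update_online(net, m, small, epochs=1, mode="gaussian", parameter=1.0)
        after = ee_objective(forward_map(net, m).coords, aff)
        assert after <= before + 1e-12

    def test_mapped_new_data_finite(self, rng):
        net = init_network(3, 2, (4,), seed=0)
        new = ExpressionMatrix(rng.normal(size=(5, 3)))
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=3, tol=0.0)
        net = update_online(net, new, cfg, mode="gaussian", parameter=1.0)
        assert np.all(np.isfinite(forward_map(net, new).coords))

    def test_dimension_mismatch(self, rng):
        net = init_network(3, 2, (4,), seed=0)
        with pytest.raises(ValueError, match="features"):
            update_online(net, ExpressionMatrix(rng.normal(size=(5, 7))), TrainConfig())
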