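"""RBM energy model, contrastive divergence, and the DBN classifier."""

import numpy as np
import pytest

from semg import (
    DBNModel,
    RBMParams,
    TrainConfig,
    cd_update,
    finetune,
    load_model,
    p_h_given_v,
    p_v_given_h,
    predict,
    pretrain,
    rbm_energy,
    rbm_joint_table,
    rbm_log_likelihood,
    save_model,
    train_dbn,
)


def random_rbm(rng, nv, nh, scale=0.8):
    return RBMParams(W=rng.normal(0, scale, (nv, nh)),
                     a=rng.normal(0, scale, nv),
                     b=rng.normal(0, scale, nh))


def energy_triple_loop(v, h, theta):
    """Naive summation oracle for the energy bilinear form."""
    e = 0.0
    for i in range(len(v)):
        e -= theta.a[i] * v[i]
    for j in range(len(h)):
        e -= theta.b[j] * h[j]
    for i in range(len(v)):
        for j in range(len(h)):
            e -= theta.W[i, j] * v[i] * h[j]
    return e


class TestEnergy:
    def test_zero_parameters_give_zero_energy(self):
        theta = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert rbm_energy([1, 0, 1], [1, 1], theta) == 0.0

    def test_hand_arithmetic(self):
        theta = RBMParams(W=[[1.0], [0.0]], a=[0.5, 0.0], b=[-0.2])
        assert rbm_energy([1, 0], [1], theta) == pytest.approx(-1.3)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            theta = random_rbm(rng, 4, 3)
            v = rng.integers(0, 2, 4).astype(float)
            h = rng.integers(0, 2, 3).astype(float)
            assert rbm_energy(v, h, theta) == pytest.approx(
                energy_triple_loop(v, h, theta), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        theta = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            rbm_energy([1, 0], [1, 1], theta)


class TestJointTable:
    def test_zero_parameters_give_uniform(self):
        theta = RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        table = rbm_joint_table(theta)
        assert np.allclose(table, 1.0 / 16)

    def test_normalization(self, rng):
        for _ in range(10):
            theta = random_rbm(rng, 3, 3)
            assert rbm_joint_table(theta).sum() == pytest.approx(1.0, abs=1e-12)

    def test_conditionals_match_sigmoid_formulas(self, rng):
        """P(h_j=1 | v) read off the enumerated joint equals the sigmoid
        conditional, and symmetrically for the visibles."""
        from semg.dbn import _binary_states
        for _ in range(10):
            theta = random_rbm(rng, 2, 2)
            table = rbm_joint_table(theta)
            V, H = _binary_states(2), _binary_states(2)
            for vi, v in enumerate(V):
                cond = table[vi] / table[vi].sum()
                for j in range(2):
                    p_marg = cond[H[:, j] == 1].sum()
                    assert p_marg == pytest.approx(p_h_given_v(v, theta)[j],
                                                   abs=1e-10)
            for hi, h in enumerate(H):
                cond = table[:, hi] / table[:, hi].sum()
                for i in range(2):
                    p_marg = cond[V[:, i] == 1].sum()
                    assert p_marg == pytest.approx(p_v_given_h(h, theta)[i],
                                                   abs=1e-10)

    def test_size_guard(self):
        theta = RBMParams(np.zeros((10, 10)), np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            rbm_joint_table(theta)


class TestConditionals:
    def test_zero_parameters_give_half(self):
        theta = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert np.allclose(p_h_given_v(np.ones(3), theta), 0.5)
        assert np.allclose(p_v_given_h(np.ones(2), theta), 0.5)

    def test_saturation(self):
        theta = RBMParams(np.zeros((2, 1)), np.zeros(2), np.array([20.0]))
        assert p_h_given_v(np.zeros(2), theta)[0] == pytest.approx(1.0, abs=1e-8)

    def test_open_interval(self, rng):
        theta = random_rbm(rng, 4, 4)
        p = p_h_given_v(rng.random(4), theta)
        assert np.all((p > 0) & (p < 1))


class TestCDUpdate:
    def test_zero_learning_rate_leaves_parameters(self, rng):
        theta = random_rbm(rng, 3, 2)
        theta2 = cd_update(rng.random((5, 3)), theta, lr=0.0,
                           rng=np.random.default_rng(0))
        assert np.array_equal(theta2.W, theta.W)
        assert np.array_equal(theta2.a, theta.a)

    def test_deterministic_given_rng_seed(self, rng):
        theta = random_rbm(rng, 3, 2)
        batch = rng.random((5, 3))
        out1 = cd_update(batch, theta, 0.1, rng=np.random.default_rng(3))
        out2 = cd_update(batch, theta, 0.1, rng=np.random.default_rng(3))
        assert np.array_equal(out1.W, out2.W)

    def test_rejects_bad_batches(self, rng):
        theta = random_rbm(rng, 3, 2)
        with pytest.raises(ValueError):
            cd_update(np.empty((0, 3)), theta, 0.1)
        with pytest.raises(ValueError):
            cd_update(np.array([[0.2, 1.5, 0.0]]), theta, 0.1)

    def test_cd_training_raises_exact_log_likelihood(self):
        """CD-1 on a 4-pattern toy distribution improves the enumerated
        log-likelihood relative to initialization in >= 4 of 5 seeds."""
        patterns = np.array([[1, 1, 0, 0], [0, 0, 1, 1],
                             [1, 1, 1, 1], [0, 0, 0, 0]], dtype=float)
        data = np.tile(patterns, (10, 1))
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            theta = RBMParams(rng.normal(0, 0.1, (4, 4)), np.zeros(4), np.zeros(4))
            ll0 = rbm_log_likelihood(patterns, theta)
            for _ in range(200):
                order = rng.permutation(len(data))
                for s in range(0, len(data), 10):
                    theta = cd_update(data[order[s:s + 10]], theta, 0.2, 1, rng)
            wins += rbm_log_likelihood(patterns, theta) > ll0
        assert wins >= 4


class TestPretrain:
    def test_stack_shapes_for_gesture_architecture(self, rng):
        """Three hidden layers of 300 units over 12 features."""
        X = rng.random((20, 12))
        cfg = TrainConfig(epochs_pretrain=1, epochs_finetune=0, seed=0)
        stack = pretrain(X, (300, 300, 300), cfg)
        assert [(t.n_visible, t.n_hidden) for t in stack] == [
            (12, 300), (300, 300), (300, 300)]

    def test_zero_epochs_returns_initialized_stack(self, rng):
        X = rng.random((10, 5))
        cfg = TrainConfig(layer_sizes=(4,), epochs_pretrain=0, seed=1)
        stack = pretrain(X, (4,), cfg)
        assert stack[0].W.shape == (5, 4)
        assert np.all(stack[0].a == 0)

    def test_reproducible_given_seed(self, rng):
        X = rng.random((16, 6))
        cfg = TrainConfig(layer_sizes=(8, 8), epochs_pretrain=3, seed=5)
        s1 = pretrain(X, (8, 8), cfg)
        s2 = pretrain(X, (8, 8), cfg)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.W, b.W)


class TestFinetuneAndPredict:
    @pytest.fixture
    def toy_features(self, rng):
        """Two linearly separable clusters in [0, 1]^4."""
        a = rng.random((30, 4)) * 0.3
        b = rng.random((30, 4)) * 0.3 + 0.65
        X = np.vstack([a, b])
        y = np.array([1] * 30 + [2] * 30)
        return X, y

    def test_separable_toy_reaches_perfect_training_accuracy(self, toy_features):
        X, y = toy_features
        cfg = TrainConfig(layer_sizes=(16,), epochs_pretrain=5,
                          epochs_finetune=200, batch_size=10, seed=0)
        model = train_dbn(X, y, cfg)
        _, labels = predict(model, X)
        assert np.mean(labels == y) == 1.0

    def test_zero_finetune_epochs_still_predicts(self, toy_features):
        X, y = toy_features
        cfg = TrainConfig(layer_sizes=(8,), epochs_pretrain=1,
                          epochs_finetune=0, seed=0)
        model = train_dbn(X, y, cfg)
        probs, labels = predict(model, X)
        assert probs.shape == (60, 2)
        assert set(labels) <= {1, 2}

    def test_probability_rows_sum_to_one_and_duplicates_match(self, toy_features):
        X, y = toy_features
        cfg = TrainConfig(layer_sizes=(8,), epochs_pretrain=1,
                          epochs_finetune=20, seed=0)
        model = train_dbn(X, y, cfg)
        probs, _ = predict(model, np.vstack([X[:3], X[:3]]))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(probs[:3], probs[3:])

    def test_reproducible_given_seed(self, toy_features):
        X, y = toy_features
        cfg = TrainConfig(layer_sizes=(8,), epochs_pretrain=2,
                          epochs_finetune=30, seed=11)
        m1 = train_dbn(X, y, cfg)
        m2 = train_dbn(X, y, cfg)
        assert np.array_equal(m1.softmax_W, m2.softmax_W)
        assert np.array_equal(m1.rbm_stack[0].W, m2.rbm_stack[0].W)

    def test_full_finetune_not_worse_than_head_only(self, toy_features):
        """End-to-end fine-tuning should match or beat training only the
        softmax head on the frozen pretrained stack."""
        X, y = toy_features
        accs = {}
        for scope in ("full", "head"):
            for seed in (0, 1, 2):
                cfg = TrainConfig(layer_sizes=(16,), epochs_pretrain=5,
                                  epochs_finetune=150, batch_size=10,
                                  seed=seed, finetune_scope=scope)
                model = train_dbn(X, y, cfg)
                _, labels = predict(model, X)
                accs.setdefault(scope, []).append(np.mean(labels == y))
        assert np.mean(accs["full"]) >= np.mean(accs["head"]) - 1e-9

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_dbn(rng.random((10, 3)), np.ones(10), TrainConfig(
                layer_sizes=(4,), epochs_pretrain=0, epochs_finetune=0))

    def test_label_mapping_preserves_original_ids(self, rng):
        X = np.vstack([rng.random((10, 3)) * 0.2,
                       rng.random((10, 3)) * 0.2 + 0.7])
        y = np.array([3] * 10 + [9] * 10)
        cfg = TrainConfig(layer_sizes=(8,), epochs_pretrain=1,
                          epochs_finetune=100, seed=0)
        model = train_dbn(X, y, cfg)
        _, labels = predict(model, X)
        assert set(labels) <= {3, 9}

    def test_dimension_mismatch_rejected(self, toy_features):
        X, y = toy_features
        cfg = TrainConfig(layer_sizes=(8,), epochs_pretrain=0,
                          epochs_finetune=0, seed=0)
        model = train_dbn(X, y, cfg)
        with pytest.raises(ValueError):
            predict(model, np.random.random((3, 7)))


class TestSerialization:
    def test_roundtrip_bit_exact(self, tmp_path, rng):
        X = np.vstack([rng.random((8, 5)) * 0.3, rng.random((8, 5)) * 0.3 + 0.6])
        y = np.array([1] * 8 + [2] * 8)
        cfg = TrainConfig(layer_sizes=(6, 4), epochs_pretrain=2,
                          epochs_finetune=10, seed=2)
        model = train_dbn(X, y, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.softmax_W, model.softmax_W)
        assert np.array_equal(back.feature_min, model.feature_min)
        assert np.array_equal(back.classes, model.classes)
        for a, b in zip(back.rbm_stack, model.rbm_stack):
            assert np.array_equal(a.W, b.W)
        p1, _ = predict(model, X)
        p2, _ = predict(back, X)
        assert np.array_equal(p1, p2)
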