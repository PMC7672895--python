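import copy
import itertools

import numpy as np
import pytest

from deepfragk.neural.dbn import dbn_pretrain
from deepfragk.neural.fold_cnn import FoldCNN, cnn_forward, train_fold_cnn
from deepfragk.neural.fragment_predictor import (FragmentPredictor,
                                                 multimodal_forward,
                                                 train_fragment_predictor)
from deepfragk.neural.ops import cross_entropy
from deepfragk.neural.rbm import (RBMParams, exact_gradient,
                                  exact_log_likelihood, rbm_cd_update)
from deepfragk.neural.training import TrainConfig, TrainingError

SMALL_ARCH = {
    "modality_dims": {"sequence": [77, 8], "physicochemical": [82, 8],
                      "evolutionary": [1600, 16]},
    "fusion_dim": 12, "head_dims": [10, 10], "n_classes": 5,
}


def small_rbm(seed=5, nv=3, nh=2):
    rng = np.random.default_rng(seed)
    return RBMParams(W=rng.normal(0, 0.5, (nv, nh)),
                     a=rng.normal(0, 0.3, nv), b=rng.normal(0, 0.3, nh))


def enumeration_oracle(params, data):
    """Gradient of the mean log-likelihood by summing over all (v, h) states."""
    nv, nh = params.W.shape
    joint = [(np.array(v, float), np.array(h, float))
             for v in itertools.product([0, 1], repeat=nv)
             for h in itertools.product([0, 1], repeat=nh)]

    def energy(v, h):
        return -(params.a @ v) - (params.b @ h) - v @ params.W @ h

    Z = sum(np.exp(-energy(v, h)) for v, h in joint)
    gW = np.zeros_like(params.W)
    ga = np.zeros_like(params.a)
    gb = np.zeros_like(params.b)
    for v, h in joint:
        p = np.exp(-energy(v, h)) / Z
        gW -= p * np.outer(v, h)
        ga -= p * v
        gb -= p * h
    for x in data:
        num_W = np.zeros_like(params.W)
        num_b = np.zeros_like(params.b)
        den = 0.0
        for h_bits in itertools.product([0, 1], repeat=nh):
            h = np.array(h_bits, float)
            p = np.exp(-energy(x, h))
            num_W += p * np.outer(x, h)
            num_b += p * h
            den += p
        gW += num_W / den / len(data)
        ga += x / len(data)
        gb += num_b / den / len(data)
    return {"W": gW, "a": ga, "b": gb}


class TestRBM:
    def test_exact_gradient_matches_enumeration_oracle(self):
        params = small_rbm()
        data = (np.random.default_rng(6).random((8, 3)) < 0.5).astype(float)
        got = exact_gradient(params, data)
        expect = enumeration_oracle(params, data)
        for key in got:
            np.testing.assert_allclose(got[key], expect[key], atol=1e-10)

    def test_exact_gradient_matches_finite_differences(self):
        params = small_rbm(seed=7)
        data = (np.random.default_rng(8).random((4, 3)) < 0.5).astype(float)
        grad = exact_gradient(params, data)
        eps = 1e-6
        for i in range(3):
            for j in range(2):
                params.W[i, j] += eps
                up = exact_log_likelihood(params, data)
                params.W[i, j] -= 2 * eps
                dn = exact_log_likelihood(params, data)
                params.W[i, j] += eps
                assert grad["W"][i, j] == pytest.approx((up - dn) / (2 * eps),
                                                        abs=1e-5)

    def test_cd1_expected_update_aligns_with_exact_gradient(self):
        params = small_rbm(seed=9)
        data = (np.random.default_rng(10).random((16, 3)) < 0.5).astype(float)
        exact = exact_gradient(params, data)
        rng = np.random.default_rng(11)
        from deepfragk.neural.rbm import _cd_statistics
        acc = None
        for _ in range(400):
            grads, _ = _cd_statistics(params, data, 1, rng)
            acc = grads if acc is None else {
                k: acc[k] + grads[k] for k in grads}
        inner = sum(float((acc[k] / 400 * exact[k]).sum()) for k in exact)
        assert inner > 0

    def test_reconstruction_error_trends_down_on_repeated_batch(self):
        rng = np.random.default_rng(12)
        params = RBMParams.initialize(6, 4, rng)
        batch = np.tile((rng.random(6) < 0.5).astype(float), (20, 1))
        cfg = TrainConfig(learning_rate=0.05, batch_size=20)
        from deepfragk.neural.ops import Adam
        opt = Adam(lr=cfg.learning_rate)
        errs = []
        for _ in range(50):
            _, err = rbm_cd_update(params, batch, cfg, rng, opt)
            errs.append(err)
        assert np.mean(errs[-10:]) < np.mean(errs[:10])

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        params = small_rbm(seed=13)
        before = copy.deepcopy(params)
        batch = np.ones((4, 3))
        rbm_cd_update(params, batch, TrainConfig(learning_rate=0.0),
                      np.random.default_rng(0))
        np.testing.assert_array_equal(params.W, before.W)
        np.testing.assert_array_equal(params.a, before.a)

    def test_batch_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbm_cd_update(small_rbm(), np.ones((2, 5)), TrainConfig(),
                          np.random.default_rng(0))


class TestDBN:
    def test_stack_shapes_chain(self, rng):
        data = rng.normal(size=(200, 9))
        stack = dbn_pretrain([9, 8, 4], data,
                             TrainConfig(learning_rate=1e-3, batch_size=50,
                                         pretrain_epochs=2), rng)
        assert stack.layer_dims == [9, 8, 4]
        assert len(stack.layers) == 2
        assert stack.transform(data).shape == (200, 4)

    def test_pretraining_is_deterministic_under_seed(self):
        data = np.random.default_rng(1).normal(size=(100, 6))
        cfg = TrainConfig(learning_rate=1e-3, batch_size=25, pretrain_epochs=2)
        s1 = dbn_pretrain([6, 4], data, cfg, np.random.default_rng(42))
        s2 = dbn_pretrain([6, 4], data, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(s1.layers[0].W, s2.layers[0].W)


class TestFragmentPredictor:
    def test_softmax_contract(self, rng):
        model = FragmentPredictor(arch=SMALL_ARCH, rng=rng)
        probs = model.predict_proba(rng.normal(size=(7, 1759)))
        assert probs.shape == (7, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_default_configuration_is_hundred_way(self):
        model = FragmentPredictor(zero_init=True)
        assert model.n_classes == 100
        assert model.params["head/0/W"].shape[1] == 1000
        assert model.params["head/1/W"].shape == (1000, 1000)

    def test_zero_weights_give_uniform_distribution(self, rng):
        model = FragmentPredictor(arch=SMALL_ARCH, zero_init=True)
        probs = model.predict_proba(rng.normal(size=(3, 1759)))
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_inference_is_deterministic(self, rng):
        model = FragmentPredictor(arch=SMALL_ARCH, rng=rng)
        x = rng.normal(size=(1, 1759))
        np.testing.assert_array_equal(model.predict_proba(x),
                                      model.predict_proba(x))

    def test_missing_feature_group_is_named(self, rng, random_fragment):
        from deepfragk.pipeline import FragmentWindow, featurize_window
        seq, prof = random_fragment(length=6, seed=3)
        fs = featurize_window(FragmentWindow(parent_id="x", start=0, length=6,
                                             sequence=seq, profile_slice=prof))
        del fs.group_spans["evolutionary"]
        model = FragmentPredictor(arch=SMALL_ARCH, rng=rng)
        with pytest.raises(ValueError, match="evolutionary"):
            multimodal_forward(model, fs)

    def test_backprop_matches_finite_differences(self, rng):
        model = FragmentPredictor(arch=SMALL_ARCH, rng=rng)
        X = rng.normal(size=(6, 1759))
        y = np.array([0, 1, 2, 3, 4, 0])
        _, grads = model.loss_and_grads(X, y, rng=rng, dropout=0.0)
        eps = 1e-6
        check = [("fusion/W", (3, 5)), ("out/W", (2, 1)),
                 ("sequence/0/W", (10, 3)), ("head/1/b", (4,))]
        for key, idx in check:
            p = model.params[key]
            orig = p[idx]
            p[idx] = orig + eps
            up = cross_entropy(model.predict_proba(X), y)
            p[idx] = orig - eps
            dn = cross_entropy(model.predict_proba(X), y)
            p[idx] = orig
            assert grads[key][idx] == pytest.approx((up - dn) / (2 * eps),
                                                    rel=1e-3, abs=1e-8)

    def test_training_requires_two_classes(self, rng):
        X = rng.normal(size=(20, 1759))
        with pytest.raises(TrainingError):
            train_fragment_predictor(X, np.zeros(20, dtype=int),
                                     TrainConfig(), arch=SMALL_ARCH)

    def test_training_is_bit_reproducible(self, rng):
        X = rng.normal(size=(60, 1759))
        y = np.arange(60) % 3
        arch = {**SMALL_ARCH, "n_classes": 3}
        cfg = TrainConfig(learning_rate=1e-3, batch_size=20, max_epochs=3,
                          patience=1, pretrain_epochs=1, seed=7)
        m1, _ = train_fragment_predictor(X, y, cfg, arch=arch)
        m2, _ = train_fragment_predictor(X, y, cfg, arch=arch)
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])


class TestFoldCNN:
    def test_documented_shape_pipeline_for_length_100(self):
        model = FoldCNN(arch={"n_input": 100, "n_folds": 27}, zero_init=True)
        assert model.arch["conv1_filters"] == 10
        assert model.shapes["conv1"] == (91, 10)
        assert model.shapes["pool1"] == (82, 10)
        assert model.shapes["stack"] == (10, 82)
        assert model.shapes["conv2"] == (1, 73, 100)
        assert model.shapes["pool2"] == (1, 14, 100)
        assert model.shapes["flatten"] == 1400

    def test_input_below_minimum_is_shape_error(self):
        with pytest.raises(ValueError, match="minimum input length is 28"):
            FoldCNN(arch={"n_input": 27, "n_folds": 3})
        FoldCNN(arch={"n_input": 28, "n_folds": 3}, zero_init=True)

    def test_zero_weights_give_uniform_softmax(self, rng):
        model = FoldCNN(arch={"n_input": 100, "n_folds": 4}, zero_init=True)
        probs = cnn_forward(model, rng.normal(size=100))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_max_pool_monotonicity(self, rng):
        # increasing any single activation never decreases any pooled value
        from deepfragk.neural.fold_cnn import _pool1d
        x = rng.normal(size=(2, 30, 4))
        base, _ = _pool1d(x, 10, 1, axis=1)
        for _ in range(20):
            y = x.copy()
            idx = (rng.integers(2), rng.integers(30), rng.integers(4))
            y[idx] = np.abs(y[idx]) * 2 + 1
            pooled, _ = _pool1d(y, 10, 1, axis=1)
            assert np.all(pooled >= base)

    def test_backprop_matches_finite_differences(self, rng):
        model = FoldCNN(arch={"n_input": 40, "n_folds": 3}, rng=rng)
        X = rng.normal(size=(5, 40))
        y = np.array([0, 1, 2, 0, 1])
        _, grads = model.loss_and_grads(X, y, rng=rng, dropout=0.0)
        eps = 1e-6
        check = [("conv1/W", (2, 3)), ("conv2/W", (5, 1, 4)),
                 ("fc0/W", (11, 7)), ("out/b", (2,))]
        for key, idx in check:
            p = model.params[key]
            orig = p[idx]
            p[idx] = orig + eps
            up = cross_entropy(model.predict_proba(X), y)
            p[idx] = orig - eps
            dn = cross_entropy(model.predict_proba(X), y)
            p[idx] = orig
            assert grads[key][idx] == pytest.approx((up - dn) / (2 * eps),
                                                    rel=1e-3, abs=1e-8)

    def test_training_is_deterministic_and_rejects_single_fold(self, rng):
        V = rng.normal(size=(40, 30))
        y = np.arange(40) % 2
        cfg = TrainConfig(learning_rate=1e-3, batch_size=10, max_epochs=3,
                          patience=1, seed=3)
        m1, _ = train_fold_cnn(V, y, cfg)
        m2, _ = train_fold_cnn(V, y, cfg)
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])
        with pytest.raises(TrainingError):
            train_fold_cnn(V, np.zeros(40, dtype=int), cfg)


class TestEarlyStopping:
    def test_patience_zero_stops_after_first_non_improving_epoch(self, rng):
        X = rng.normal(size=(30, 1759))
        y = np.arange(30) % 2
        arch = {**SMALL_ARCH, "n_classes": 2}
        # zero learning rate: no epoch can improve, so training must stop
        # right after the first non-improving epoch
        cfg = TrainConfig(learning_rate=0.0, batch_size=10, max_epochs=50,
                          patience=0, pretrain_epochs=0, seed=1)
        _, hist = train_fragment_predictor(X, y, cfg, arch=arch,
                                           pretrain=False)
        assert len(hist["train_loss"]) == 2
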