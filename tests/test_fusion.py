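"""Cross-entropy, logit fusion and the weighted three-term joint loss."""

import logging

import numpy as np
import pytest

from depfuse.architectures import ArchitectureSpec, build_dgdn3d, build_sadn2d
from depfuse.dbn import FineTuneConfig
from depfuse.errors import DimensionMismatchError, InvalidInputError
from depfuse.fusion import (
    FusionConfig,
    JointNetwork,
    SessionFeatures,
    cross_entropy,
    fit_joint,
    fused_loss,
    fused_probability,
    init_joint,
    joint_forward,
    joint_param_arrays,
    logit,
    predict,
)

MICRO = ArchitectureSpec(
    image_size=4,
    sadn_sizes=(5, 4),
    dgdn_sizes=(6, 5, 4, 3),
    top_rbm_hidden=3,
    lstm_units=(4, 2),
    n_landmarks=3,
    n_aus=2,
)


def micro_network(seed=0):
    rng = np.random.default_rng(seed)
    sadn = build_sadn2d(MICRO, rng)
    dgdn = build_dgdn3d(MICRO, "au-4dbn-lstm", rng)
    return init_joint(sadn, dgdn, rng)


def micro_session(seed=0, label=1, T=3):
    rng = np.random.default_rng(seed)
    return SessionFeatures(
        channels=rng.normal(size=(3, T, MICRO.image_dim)),
        frames3d=rng.normal(size=(T, MICRO.landmark_dim)),
        aus=rng.uniform(-1, 1, size=(T, MICRO.n_aus)),
        label=label,
    )


class TestCrossEntropy:
    def test_near_perfect_prediction_near_zero(self):
        assert cross_entropy([1.0], [1.0 - 1e-12]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_closed_form(self):
        assert cross_entropy([1.0, 0.0], [0.5, 0.5]) == pytest.approx(2 * np.log(2))

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 2, 10).astype(float)
        p = rng.uniform(0.05, 0.95, 10)
        perm = rng.permutation(10)
        assert cross_entropy(y, p) == pytest.approx(cross_entropy(y[perm], p[perm]))

    def test_exact_zero_or_one_clamped_with_log(self, caplog):
        with caplog.at_level(logging.WARNING, logger="depfuse.fusion"):
            val = cross_entropy([1.0], [1.0])
        assert np.isfinite(val)
        assert any("clamping" in r.message for r in caplog.records)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_entropy([1.0], [1.5])


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit(0.5) == 0.0

    def test_closed_form(self):
        assert logit(0.73) == pytest.approx(np.log(0.73 / 0.27), abs=1e-12)

    def test_sigmoid_inverse_identity(self):
        sig = lambda z: 1 / (1 + np.exp(-z))
        for p in np.arange(0.01, 1.0, 0.07):
            assert sig(logit(p)) == pytest.approx(p, abs=1e-12)

    def test_rejects_boundary(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(InvalidInputError):
                logit(bad)


class TestFusedProbability:
    def test_half_is_identity(self):
        for p in (0.1, 0.42, 0.9):
            assert fused_probability(0.5, p) == pytest.approx(p, abs=1e-12)

    def test_equal_inputs_closed_form(self):
        sig = lambda z: 1 / (1 + np.exp(-z))
        assert fused_probability(0.73, 0.73) == pytest.approx(
            sig(2 * np.log(0.73 / 0.27)), abs=1e-12
        )
        assert fused_probability(0.73, 0.73) == pytest.approx(0.8796, abs=5e-4)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.uniform(0.05, 0.95, 2)
            assert fused_probability(a, b) == pytest.approx(fused_probability(b, a))

    def test_linear_head_identity(self, rng):
        # sigma(l(sig(s1)) + l(sig(s2))) == sigma(s1 + s2) for raw scores
        sig = lambda z: 1 / (1 + np.exp(-z))
        s1, s2 = rng.normal(size=2)
        assert fused_probability(sig(s1), sig(s2)) == pytest.approx(sig(s1 + s2), abs=1e-12)


class TestFusedLoss:
    def test_weighted_sum_arithmetic(self):
        net = micro_network()
        batch = [micro_session(1, 1), micro_session(2, 0)]
        parts = []
        for lam in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            l, _ = fused_loss(batch, net, FusionConfig(*lam))
            parts.append(l)
        total, _ = fused_loss(batch, net, FusionConfig(1.0, 1.0, 0.1))
        assert total == pytest.approx(parts[0] + parts[1] + 0.1 * parts[2], rel=1e-12)

    def test_lambda3_zero_kills_joint_head_gradient(self):
        net = micro_network()
        _, grads = fused_loss([micro_session()], net, FusionConfig(1.0, 1.0, 0.0))
        assert np.allclose(grads["joint.w"], 0.0)
        assert grads["joint.b"] == 0.0

    def test_stream_head_gradients_vanish_without_stream_losses(self):
        net = micro_network()
        _, grads = fused_loss([micro_session()], net, FusionConfig(0.0, 0.0, 0.1))
        assert np.allclose(grads["ch0.head_w"], 0.0)
        assert np.allclose(grads["head3d.w"], 0.0)
        assert not np.allclose(grads["joint.w"], 0.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(InvalidInputError):
            fused_loss([], micro_network(), FusionConfig())

    def test_finite_difference_total_gradient(self):
        net = micro_network(3)
        batch = [micro_session(5, 1, T=2), micro_session(6, 0, T=2)]
        cfg = FusionConfig(1.0, 1.0, 0.1)
        loss, grads = fused_loss(batch, net, cfg)
        params = joint_param_arrays(net)
        eps = 1e-6
        checked = [
            ("ch1.w0", (2, 1)),
            ("ch0.head_w", (0,)),
            ("base.w0", (4, 2)),
            ("top.w", (1, 1)),
            ("lstm0.w_xf", (0, 1)),
            ("lstm1.w_ho", (1, 0)),
            ("head3d.w", (1,)),
            ("joint.w", (2,)),
        ]
        for key, idx in checked:
            arr = params[key]
            orig = arr[idx]
            arr[idx] = orig + eps
            lp, _ = fused_loss(batch, net, cfg)
            arr[idx] = orig - eps
            lm, _ = fused_loss(batch, net, cfg)
            arr[idx] = orig
            fd = (lp - lm) / (2 * eps)
            got = grads[key][idx]
            # abs floor covers central-difference truncation noise on
            # near-zero entries
            assert got == pytest.approx(fd, rel=1e-5, abs=5e-9), key
        # scalar joint-head bias needs reconstruction (frozen dataclass)
        from dataclasses import replace as drep

        lp, _ = fused_loss(batch, drep(net, joint_bias=net.joint_bias + eps), cfg)
        lm, _ = fused_loss(batch, drep(net, joint_bias=net.joint_bias - eps), cfg)
        assert float(grads["joint.b"]) == pytest.approx(
            (lp - lm) / (2 * eps), rel=1e-5, abs=5e-9
        )

    def test_batched_equals_sequential(self):
        net = micro_network(4)
        sessions = [micro_session(i, i % 2) for i in range(4)]
        loss_all, grads_all = fused_loss(sessions, net, FusionConfig())
        acc = None
        total = 0.0
        for s in sessions:
            l, g = fused_loss([s], net, FusionConfig())
            total += l
            acc = g if acc is None else {k: acc[k] + g[k] for k in g}
        assert loss_all == pytest.approx(total / 4)
        for k in grads_all:
            assert np.allclose(grads_all[k], np.asarray(acc[k]) / 4, atol=1e-10), k


class TestPredictAndTraining:
    def test_decision_thresholds(self):
        net = micro_network()
        s = micro_session()
        cache = joint_forward(net, s)
        cls = predict(net, s)
        assert cls == int(cache["p_fused"] >= 0.5)

    def test_loss_decreases_on_separable_data(self):
        ok = 0
        for seed in range(5):
            net = micro_network(seed)
            rng = np.random.default_rng(seed)
            sessions = []
            for i in range(12):
                label = i % 2
                s = micro_session(100 + i, label)
                shifted = SessionFeatures(
                    channels=s.channels + (2.0 if label else -2.0),
                    frames3d=s.frames3d + (1.0 if label else -1.0),
                    aus=s.aus,
                    label=label,
                )
                sessions.append(shifted)
            net2, hist = fit_joint(
                net, sessions, FusionConfig(),
                FineTuneConfig(epochs=25, learning_rate=0.05, minibatch_size=6),
                rng,
            )
            ok += hist[-1] < hist[0]
        assert ok >= 3

    def test_freeze_prefixes_hold_parameters(self):
        net = micro_network(1)
        sessions = [micro_session(i, i % 2) for i in range(4)]
        net2, _ = fit_joint(
            net, sessions, FusionConfig(),
            FineTuneConfig(epochs=2, learning_rate=0.2, minibatch_size=4),
            np.random.default_rng(0),
            freeze=("ch", "joint"),
        )
        assert np.array_equal(net2.sadn.channel_models[0].layers[0].weights,
                              net.sadn.channel_models[0].layers[0].weights)
        assert np.array_equal(net2.joint_weights, net.joint_weights)
        assert not np.array_equal(net2.dgdn.lstm_head_weights, net.dgdn.lstm_head_weights)

    def test_misaligned_session_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidInputError):
            SessionFeatures(
                channels=rng.normal(size=(3, 4, MICRO.image_dim)),
                frames3d=rng.normal(size=(3, MICRO.landmark_dim)),
                aus=rng.normal(size=(4, MICRO.n_aus)),
                label=0,
            )
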