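"""RBM energies, conditionals, Gibbs sampling and CD updates."""

import numpy as np
import pytest
from dataclasses import replace

from depfuse.errors import (
    ConfigurationError,
    DimensionMismatchError,
    InvalidInputError,
)
from depfuse.rbm import (
    BERNOULLI,
    GAUSSIAN,
    CdConfig,
    RbmParams,
    absorb_input_affine,
    cd_update,
    gibbs_step,
    hidden_conditional,
    init_rbm,
    rbm_energy,
    train_rbm,
    reconstruction_error,
    visible_conditional,
)


def make_rbm(w, a, b, sigma=1.0, family=GAUSSIAN):
    return RbmParams(
        weights=np.atleast_2d(np.asarray(w, dtype=float)),
        visible_bias=np.atleast_1d(np.asarray(a, dtype=float)),
        hidden_bias=np.atleast_1d(np.asarray(b, dtype=float)),
        sigma=sigma,
        visible_family=family,
    )


class TestEnergy:
    def test_gaussian_zero_at_bias_with_no_hidden(self):
        p = make_rbm([[0.7]], [1.3], [0.2], sigma=0.5)
        assert rbm_energy(np.array([1.3]), np.array([0.0]), p) == 0.0

    def test_gaussian_hand_value(self):
        p = make_rbm([[1.0]], [0.0], [0.0], sigma=1.0)
        # (2-0)^2/2 - 1*2*1 - 0 = 0
        assert rbm_energy(np.array([2.0]), np.array([1.0]), p) == pytest.approx(0.0)

    def test_bernoulli_hand_value(self):
        p = make_rbm([[1.0], [1.0]], [0.0, 0.0], [0.0], family=BERNOULLI)
        assert rbm_energy(np.array([1.0, 1.0]), np.array([1.0]), p) == pytest.approx(-2.0)

    def test_dimension_mismatch(self):
        p = make_rbm([[1.0]], [0.0], [0.0])
        with pytest.raises(DimensionMismatchError):
            rbm_energy(np.array([1.0, 2.0]), np.array([1.0]), p)


def enumerate_hidden_conditional(v, params):
    """Oracle: P(h_j = 1 | v) by brute-force normalization of exp(-E)."""
    n = params.n_hidden
    weights = []
    states = []
    for idx in range(2**n):
        h = np.array([(idx >> j) & 1 for j in range(n)], dtype=float)
        states.append(h)
        weights.append(np.exp(-rbm_energy(v, h, params)))
    weights = np.array(weights)
    weights /= weights.sum()
    return np.array(
        [sum(w for w, h in zip(weights, states) if h[j] == 1) for j in range(n)]
    )


def enumerate_visible_conditional_bernoulli(h, params):
    m = params.n_visible
    weights, states = [], []
    for idx in range(2**m):
        v = np.array([(idx >> i) & 1 for i in range(m)], dtype=float)
        states.append(v)
        weights.append(np.exp(-rbm_energy(v, h, params)))
    weights = np.array(weights)
    weights /= weights.sum()
    return np.array(
        [sum(w for w, v in zip(weights, states) if v[i] == 1) for i in range(m)]
    )


class TestConditionals:
    def test_zero_weights_give_half(self):
        p = make_rbm(np.zeros((3, 4)), np.zeros(3), np.zeros(4))
        assert np.allclose(hidden_conditional(np.ones(3), p), 0.5)

    def test_saturation(self):
        p = make_rbm(np.zeros((2, 2)), np.zeros(2), np.full(2, 20.0))
        assert np.all(hidden_conditional(np.zeros(2), p) > 1 - 1e-8)

    @pytest.mark.parametrize("family", [BERNOULLI, GAUSSIAN])
    @pytest.mark.parametrize("sigma", [1.0, 0.7])
    def test_hidden_conditional_matches_enumeration(self, family, sigma, rng):
        if family == BERNOULLI and sigma != 1.0:
            pytest.skip("sigma ignored for bernoulli units")
        p = make_rbm(
            rng.normal(0, 0.5, (3, 2)), rng.normal(0, 0.5, 3), rng.normal(0, 0.5, 2),
            sigma=sigma, family=family,
        )
        v = rng.normal(0, 1, 3) if family == GAUSSIAN else rng.integers(0, 2, 3).astype(float)
        expected = enumerate_hidden_conditional(v, p)
        assert np.allclose(hidden_conditional(v, p), expected, atol=1e-10)

    def test_visible_conditional_bernoulli_matches_enumeration(self, rng):
        p = make_rbm(
            rng.normal(0, 0.5, (3, 2)), rng.normal(0, 0.5, 3), rng.normal(0, 0.5, 2),
            family=BERNOULLI,
        )
        h = np.array([1.0, 0.0])
        expected = enumerate_visible_conditional_bernoulli(h, p)
        assert np.allclose(visible_conditional(h, p), expected, atol=1e-10)

    def test_visible_conditional_gaussian_moments_by_quadrature(self, rng):
        # m = 1: integrate exp(-E(v, h)) over v on a dense grid
        p = make_rbm(rng.normal(0, 0.5, (1, 2)), [0.3], rng.normal(0, 0.5, 2), sigma=0.8)
        h = np.array([1.0, 1.0])
        grid = np.linspace(-10, 10, 200001)
        dens = np.array([np.exp(-rbm_energy(np.array([v]), h, p)) for v in grid[::100]])
        sub = grid[::100]
        dens /= np.trapezoid(dens, sub)
        mean_num = np.trapezoid(sub * dens, sub)
        var_num = np.trapezoid((sub - mean_num) ** 2 * dens, sub)
        mean, var = visible_conditional(h, p)
        assert mean[0] == pytest.approx(mean_num, abs=1e-6)
        assert var == pytest.approx(var_num, abs=1e-4)

    def test_gaussian_mean_hand_value(self):
        p = make_rbm([[2.0, -1.0]], [1.0], [0.0, 0.0])
        mean, var = visible_conditional(np.array([1.0, 1.0]), p)
        assert mean[0] == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_zero_hidden_returns_bias_and_sigma2(self):
        p = make_rbm(np.ones((2, 2)), [0.5, -0.5], np.zeros(2), sigma=2.0)
        mean, var = visible_conditional(np.zeros(2), p)
        assert np.allclose(mean, [0.5, -0.5])
        assert var == pytest.approx(4.0)


class TestGibbs:
    def test_determinism_under_seed(self, rng):
        p = init_rbm(4, 3, GAUSSIAN, rng)
        v = rng.normal(size=4)
        h1, v1 = gibbs_step(v, p, np.random.default_rng(42))
        h2, v2 = gibbs_step(v, p, np.random.default_rng(42))
        assert np.array_equal(h1, h2) and np.array_equal(v1, v2)

    def test_gaussian_reconstruction_mean(self):
        p = make_rbm(np.zeros((2, 2)), np.zeros(2), np.zeros(2), sigma=1.0)
        r = np.random.default_rng(3)
        draws = np.array([gibbs_step(np.zeros(2), p, r)[1] for _ in range(5000)])
        assert abs(draws.mean()) < 4.0 / np.sqrt(5000 * 2)

    def test_hidden_saturation_low_bias(self):
        p = make_rbm(np.zeros((2, 3)), np.zeros(2), np.full(3, -20.0), family=BERNOULLI)
        h, _ = gibbs_step(np.ones(2), p, np.random.default_rng(0))
        assert np.all(h == 0.0)


def oracle_cd1(params, batch, cfg, rng):
    """Straight-line CD-1 transcription sharing the documented rng order."""
    x = np.atleast_2d(batch)
    s2 = params.sigma**2 if params.visible_family == GAUSSIAN else 1.0
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    ph = sig(x @ params.weights / s2 + params.hidden_bias)
    h = (rng.uniform(size=ph.shape) < ph).astype(float)
    if params.visible_family == GAUSSIAN:
        v1 = h @ params.weights.T + params.visible_bias + params.sigma * rng.standard_normal(x.shape)
    else:
        pv = sig(h @ params.weights.T + params.visible_bias)
        v1 = (rng.uniform(size=pv.shape) < pv).astype(float)
    ph1 = sig(v1 @ params.weights / s2 + params.hidden_bias)
    B = x.shape[0]
    gw = (x.T @ ph - v1.T @ ph1) / (B * s2)
    ga = (x - v1).mean(axis=0) / s2
    gb = (ph - ph1).mean(axis=0)
    return (
        params.weights + cfg.learning_rate * gw,
        params.visible_bias + cfg.learning_rate * ga,
        params.hidden_bias + cfg.learning_rate * gb,
    )


class TestCdUpdate:
    def test_zero_learning_rate_is_identity(self, rng):
        p = init_rbm(3, 2, BERNOULLI, rng)
        batch = rng.integers(0, 2, (5, 3)).astype(float)
        cfg = CdConfig(learning_rate=0.0, sparsity_weight=0.0)
        out, _ = cd_update(p, batch, cfg, np.random.default_rng(0))
        assert np.array_equal(out.weights, p.weights)
        assert np.array_equal(out.hidden_bias, p.hidden_bias)

    @pytest.mark.parametrize("family", [BERNOULLI, GAUSSIAN])
    def test_matches_straight_line_cd1_oracle(self, family, rng):
        p = init_rbm(4, 3, family, rng, weight_scale=0.3)
        batch = (
            rng.integers(0, 2, (6, 4)).astype(float)
            if family == BERNOULLI
            else rng.normal(size=(6, 4))
        )
        cfg = CdConfig(k_steps=1, learning_rate=0.1, sparsity_weight=0.0, momentum=0.0)
        out, _ = cd_update(p, batch, cfg, np.random.default_rng(99))
        w, a, b = oracle_cd1(p, batch, cfg, np.random.default_rng(99))
        assert np.allclose(out.weights, w, atol=1e-12)
        assert np.allclose(out.visible_bias, a, atol=1e-12)
        assert np.allclose(out.hidden_bias, b, atol=1e-12)

    def test_input_params_not_mutated(self, rng):
        p = init_rbm(3, 2, GAUSSIAN, rng)
        w0 = p.weights.copy()
        cd_update(p, rng.normal(size=(4, 3)), CdConfig(), np.random.default_rng(0))
        assert np.array_equal(p.weights, w0)

    def test_empty_minibatch_rejected(self, rng):
        p = init_rbm(3, 2, GAUSSIAN, rng)
        with pytest.raises(InvalidInputError):
            cd_update(p, np.empty((0, 3)), CdConfig(), np.random.default_rng(0))

    def test_training_reduces_reconstruction_error(self):
        # 2-d Gaussian blob: error after 50 epochs < after 1, >= 9/10 seeds
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = r.normal(0, 1, (80, 2)) * [1.5, 0.3]
            p = init_rbm(2, 4, GAUSSIAN, r)
            cfg1 = CdConfig(epochs=1, sparsity_weight=0.0, minibatch_size=20)
            cfg50 = CdConfig(epochs=50, sparsity_weight=0.0, minibatch_size=20)
            e1 = reconstruction_error(train_rbm(data, p, cfg1, np.random.default_rng(seed)), data)
            e50 = reconstruction_error(train_rbm(data, p, cfg50, np.random.default_rng(seed)), data)
            wins += e50 < e1
        assert wins >= 9

    def test_sparsity_pushes_hidden_activity_toward_target(self, rng):
        data = rng.normal(size=(100, 5))
        p = init_rbm(5, 8, GAUSSIAN, rng)
        cfg = CdConfig(epochs=40, sparsity_weight=3.0, sparsity_target=0.1, minibatch_size=25)
        trained = train_rbm(data, p, cfg, np.random.default_rng(0))
        mean_act = hidden_conditional(data, trained).mean()
        assert abs(mean_act - 0.1) < 0.15


class TestConfigValidation:
    def test_bad_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            make_rbm([[1.0]], [0.0], [0.0], sigma=0.0)

    def test_bias_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            RbmParams(np.zeros((2, 2)), np.zeros(3), np.zeros(2))

    def test_bad_cd_config(self):
        with pytest.raises(ConfigurationError):
            CdConfig(momentum=1.5)
        with pytest.raises(ConfigurationError):
            CdConfig(sparsity_target=0.0)


class TestAbsorbAffine:
    def test_recognition_direction_exact(self, rng):
        p = init_rbm(4, 3, GAUSSIAN, rng, weight_scale=0.5)
        mu, sd = rng.normal(size=4), rng.uniform(0.5, 2.0, 4)
        x = rng.normal(size=(6, 4))
        absorbed = absorb_input_affine(p, mu, sd)
        assert np.allclose(
            hidden_conditional(x, absorbed),
            hidden_conditional((x - mu) / sd, p),
            atol=1e-12,
        )
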