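"""Restricted Boltzmann machines with Bernoulli or Gaussian visible units.

The Gaussian–Bernoulli RBM is the first layer of every deep belief network
in the package (inputs are z-scored real vectors); all higher layers are
Bernoulli–Bernoulli. The energy of a joint configuration (v, h) is

    gaussian :  E(v, h) = sum_i (v_i - a_i)^2 / (2 sigma^2)
                          - (1/sigma^2) sum_ij w_ij v_i h_j
                          - sum_j b_j h_j
    bernoulli:  E(v, h) = - a.v - b.h - v.W.h

which yields the conditionals

    P(h_j = 1 | v) = sigmoid((W^T v)_j / sigma^2 + b_j)
    P(v | h)       = N(a + W h, sigma^2 I)      (gaussian)
    P(v_i = 1 | h) = sigmoid(a_i + (W h)_i)     (bernoulli)

Training is contrastive divergence (CD-k) with momentum, optional L2 weight
decay and an optional sparsity penalty that nudges the mean hidden
activation toward a target by adjusting the hidden-bias gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DimensionMismatchError, InvalidInputError

__all__ = [
    "RbmParams",
    "CdConfig",
    "init_rbm",
    "rbm_energy",
    "hidden_conditional",
    "visible_conditional",
    "gibbs_step",
    "cd_update",
    "train_rbm",
    "reconstruction_error",
]

GAUSSIAN = "gaussian"
BERNOULLI = "bernoulli"

_sigmoid = lambda z: 0.5 * (1.0 + np.tanh(0.5 * z))  # overflow-safe logistic


@dataclass(frozen=True)
class RbmParams:
    """Parameters of one RBM layer.

    weights: (m visible, n hidden); visible_bias: (m,); hidden_bias: (n,).
    sigma is the shared visible-unit standard deviation (Gaussian family
    only; ignored for Bernoulli units).
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    sigma: float = 1.0
    visible_family: str = GAUSSIAN

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        a = np.asarray(self.visible_bias, dtype=float)
        b = np.asarray(self.hidden_bias, dtype=float)
        if w.ndim != 2:
            raise ConfigurationError("weights must be a 2-D (visible x hidden) matrix")
        if a.shape != (w.shape[0],) or b.shape != (w.shape[1],):
            raise ConfigurationError(
                f"bias shapes {a.shape}/{b.shape} inconsistent with weights {w.shape}"
            )
        if self.visible_family not in (GAUSSIAN, BERNOULLI):
            raise ConfigurationError(f"unknown visible family {self.visible_family!r}")
        if self.visible_family == GAUSSIAN and not self.sigma > 0:
            raise ConfigurationError("sigma must be positive for gaussian visible units")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "visible_bias", a)
        object.__setattr__(self, "hidden_bias", b)

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class CdConfig:
    """Contrastive-divergence training configuration.

    Defaults follow the study setup: learning rate 0.02, momentum 0.9,
    100 epochs, sparsity target 0.1 with weight 3 (applied only to the
    layers a trainer designates), minibatch updates.
    """

    k_steps: int = 1
    learning_rate: float = 0.02
    sparsity_target: float = 0.1
    sparsity_weight: float = 3.0
    weight_decay: float = 0.0
    momentum: float = 0.9
    minibatch_size: int = 50
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_steps < 1 or self.minibatch_size < 1 or self.epochs < 0:
            raise ConfigurationError("k_steps/minibatch_size/epochs must be positive")
        if self.learning_rate < 0 or self.sparsity_weight < 0 or self.weight_decay < 0:
            raise ConfigurationError("rates and penalty weights must be nonnegative")
        if not 0.0 < self.sparsity_target < 1.0:
            raise ConfigurationError("sparsity_target must lie in (0,1)")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must lie in [0,1)")


def init_rbm(
    n_visible: int,
    n_hidden: int,
    visible_family: str = GAUSSIAN,
    rng: np.random.Generator | None = None,
    weight_scale: float = 0.01,
    sigma: float = 1.0,
    dtype=np.float64,
) -> RbmParams:
    """Initialize weights ~ N(0, weight_scale) and zero biases."""
    if n_visible < 1 or n_hidden < 1:
        raise ConfigurationError("layer sizes must be positive")
    rng = np.random.default_rng(rng)
    w = rng.normal(0.0, weight_scale, size=(n_visible, n_hidden)).astype(dtype)
    return RbmParams(
        weights=w,
        visible_bias=np.zeros(n_visible, dtype=dtype),
        hidden_bias=np.zeros(n_hidden, dtype=dtype),
        sigma=sigma,
        visible_family=visible_family,
    )


def _check_v(v: np.ndarray, params: RbmParams) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise DimensionMismatchError(
            f"visible vector length {v.shape[-1]} != {params.n_visible}"
        )
    return v


def _check_h(h: np.ndarray, params: RbmParams) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise DimensionMismatchError(
            f"hidden vector length {h.shape[-1]} != {params.n_hidden}"
        )
    return h


def rbm_energy(v: np.ndarray, h: np.ndarray, params: RbmParams) -> float:
    """Energy E(v, h) of a joint configuration."""
    v = _check_v(v, params)
    h = _check_h(h, params)
    coupling = float(v @ params.weights @ h)
    if params.visible_family == GAUSSIAN:
        s2 = params.sigma**2
        quad = float(np.sum((v - params.visible_bias) ** 2)) / (2.0 * s2)
        return quad - coupling / s2 - float(params.hidden_bias @ h)
    return (
        -float(params.visible_bias @ v)
        - float(params.hidden_bias @ h)
        - coupling
    )


def hidden_conditional(v: np.ndarray, params: RbmParams) -> np.ndarray:
    """P(h_j = 1 | v); accepts a single vector or a (batch, m) matrix."""
    v = _check_v(v, params)
    s2 = params.sigma**2 if params.visible_family == GAUSSIAN else 1.0
    return _sigmoid((v @ params.weights) / s2 + params.hidden_bias)


def visible_conditional(h: np.ndarray, params: RbmParams):
    """Parameters of P(v | h).

    Gaussian family: returns (means, variance) with variance = sigma^2.
    Bernoulli family: returns the vector of P(v_i = 1 | h).
    """
    h = _check_h(h, params)
    act = h @ params.weights.T + params.visible_bias
    if params.visible_family == GAUSSIAN:
        return act, params.sigma**2
    return _sigmoid(act)


def gibbs_step(v: np.ndarray, params: RbmParams, rng: np.random.Generator):
    """One block Gibbs sweep v -> h -> v'.

    Random-draw order (relied on by independent oracles sharing the rng
    stream): first a uniform array shaped like the hidden probabilities to
    sample h, then either a standard-normal array (gaussian) or a uniform
    array (bernoulli) shaped like the visible units to sample v'.
    """
    v = _check_v(v, params)
    ph = hidden_conditional(v, params)
    h = (rng.uniform(size=ph.shape) < ph).astype(float)
    if params.visible_family == GAUSSIAN:
        mean, var = visible_conditional(h, params)
        v_new = mean + np.sqrt(var) * rng.standard_normal(mean.shape)
    else:
        pv = visible_conditional(h, params)
        v_new = (rng.uniform(size=pv.shape) < pv).astype(float)
    return h, v_new


def cd_update(
    params: RbmParams,
    minibatch: np.ndarray,
    cfg: CdConfig,
    rng: np.random.Generator,
    velocity: dict[str, np.ndarray] | None = None,
) -> tuple[RbmParams, dict[str, np.ndarray]]:
    """One CD-k parameter update from a minibatch (rows are samples).

    Positive-phase statistics use the hidden probabilities of the data;
    the negative phase runs ``cfg.k_steps`` Gibbs sweeps starting from the
    data and uses the hidden probabilities of the final reconstruction.
    Gradients are averaged over the minibatch; the update uses momentum
    (velocity = momentum * velocity + gradient; param += lr * velocity).
    Input ``params`` is never mutated.
    """
    x = np.atleast_2d(np.asarray(minibatch, dtype=float))
    if x.size == 0:
        raise InvalidInputError("empty minibatch")
    x = _check_v(x, params)
    batch = x.shape[0]
    s2 = params.sigma**2 if params.visible_family == GAUSSIAN else 1.0

    ph_data = hidden_conditional(x, params)
    v_model = x
    for _ in range(cfg.k_steps):
        _, v_model = gibbs_step(v_model, params, rng)
    ph_model = hidden_conditional(v_model, params)

    grad_w = (x.T @ ph_data - v_model.T @ ph_model) / (batch * s2)
    grad_a = np.mean(x - v_model, axis=0) / s2
    grad_b = np.mean(ph_data - ph_model, axis=0)
    if cfg.sparsity_weight > 0:
        grad_b = grad_b + cfg.sparsity_weight * (
            cfg.sparsity_target - float(np.mean(ph_data))
        )
    if cfg.weight_decay > 0:
        grad_w = grad_w - cfg.weight_decay * params.weights

    if velocity is None:
        velocity = {
            "w": np.zeros_like(params.weights),
            "a": np.zeros_like(params.visible_bias),
            "b": np.zeros_like(params.hidden_bias),
        }
    vel = {
        "w": cfg.momentum * velocity["w"] + grad_w,
        "a": cfg.momentum * velocity["a"] + grad_a,
        "b": cfg.momentum * velocity["b"] + grad_b,
    }
    new = replace(
        params,
        weights=params.weights + cfg.learning_rate * vel["w"],
        visible_bias=params.visible_bias + cfg.learning_rate * vel["a"],
        hidden_bias=params.hidden_bias + cfg.learning_rate * vel["b"],
    )
    return new, vel


def absorb_input_affine(
    params: RbmParams, mu: np.ndarray, sd: np.ndarray
) -> RbmParams:
    """Fold an input standardization z = (x - mu) / sd into the parameters.

    The returned RBM computes, on raw x, exactly the hidden conditional the
    original computed on z (the recognition direction); the generative
    direction is mapped back approximately (visible bias re-expressed in
    x units). Used when greedy pretraining standardizes intermediate
    representations for numerical conditioning.
    """
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    s2 = params.sigma**2 if params.visible_family == GAUSSIAN else 1.0
    return replace(
        params,
        weights=params.weights / sd[:, None],
        hidden_bias=params.hidden_bias - ((mu / sd) @ params.weights) / s2,
        visible_bias=mu + sd * params.visible_bias,
    )


def reconstruction_error(params: RbmParams, data: np.ndarray) -> float:
    """Mean squared error between data and its one-sweep mean reconstruction."""
    x = np.atleast_2d(np.asarray(data, dtype=float))
    ph = hidden_conditional(x, params)
    recon = ph @ params.weights.T + params.visible_bias
    if params.visible_family == BERNOULLI:
        recon = _sigmoid(recon)
    return float(np.mean((x - recon) ** 2))


def train_rbm(
    data: np.ndarray,
    params: RbmParams,
    cfg: CdConfig,
    rng: np.random.Generator,
    track_error: bool = False,
):
    """Train an RBM with minibatch CD for ``cfg.epochs`` epochs.

    Rows of ``data`` are shuffled each epoch with ``rng``. Returns the
    trained parameters, or ``(params, per-epoch reconstruction MSE)`` when
    ``track_error`` is set.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] == 0:
        raise InvalidInputError("empty training set")
    velocity = None
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(x.shape[0])
        for start in range(0, x.shape[0], cfg.minibatch_size):
            batch = x[order[start : start + cfg.minibatch_size]]
            params, velocity = cd_update(params, batch, cfg, rng, velocity)
        if track_error:
            history.append(reconstruction_error(params, x))
    if track_error:
        return params, history
    return params
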