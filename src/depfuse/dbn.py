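"""Greedy layer-wise deep belief networks with a sigmoid classification head.

A ``DbnModel`` is an ordered stack of RBM layers (the first with Gaussian
visible units over z-scored inputs, the rest Bernoulli) plus a logistic
output unit on the top-layer activation. Pretraining trains each RBM on the
mean-field hidden representation of its predecessor (a configuration switch
selects sampled representations instead); inference is a deterministic
mean-field pass. Supervised fine-tuning minimizes binary cross-entropy by
backpropagation through every layer and the head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import rbm as _rbm
from .errors import ConfigurationError, DimensionMismatchError, InvalidInputError
from .rbm import BERNOULLI, GAUSSIAN, CdConfig, RbmParams, _sigmoid

__all__ = [
    "DbnModel",
    "FineTuneConfig",
    "init_dbn",
    "pretrain_dbn",
    "dbn_forward",
    "dbn_forward_batch",
    "dbn_backward",
    "dbn_loss_and_grads",
    "fine_tune",
]


@dataclass(frozen=True)
class DbnModel:
    """Stack of RBM layers plus a logistic head on the top activation."""

    layers: tuple[RbmParams, ...]
    head_weights: np.ndarray
    head_bias: float

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("a DBN needs at least one layer")
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.n_hidden != upper.n_visible:
                raise ConfigurationError(
                    f"layer dimensions do not chain: {lower.n_hidden} -> {upper.n_visible}"
                )
        hw = np.asarray(self.head_weights, dtype=float)
        if hw.shape != (self.layers[-1].n_hidden,):
            raise ConfigurationError("head weight length must equal the top layer size")
        object.__setattr__(self, "head_weights", hw)
        object.__setattr__(self, "head_bias", float(self.head_bias))

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]

    @property
    def n_input(self) -> int:
        return self.layers[0].n_visible

    @property
    def top_dim(self) -> int:
        return self.layers[-1].n_hidden


@dataclass(frozen=True)
class FineTuneConfig:
    """SGD-with-momentum settings for supervised backprop fine-tuning."""

    learning_rate: float = 0.05
    epochs: int = 100
    minibatch_size: int = 50
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.epochs < 0 or self.minibatch_size < 1:
            raise ConfigurationError("invalid fine-tune configuration")
        if self.weight_decay < 0:
            raise ConfigurationError("weight_decay must be nonnegative")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigurationError("momentum must lie in [0,1)")


def init_dbn(
    n_input: int,
    layer_sizes: list[int],
    rng: np.random.Generator | None = None,
    input_family: str = GAUSSIAN,
    weight_scale: float = 0.01,
    dtype=np.float64,
) -> DbnModel:
    """Randomly initialized DBN (no pretraining)."""
    if not layer_sizes or any(s <= 0 for s in layer_sizes):
        raise ConfigurationError("layer sizes must be positive")
    rng = np.random.default_rng(rng)
    layers = []
    prev = n_input
    for idx, size in enumerate(layer_sizes):
        family = input_family if idx == 0 else BERNOULLI
        layers.append(
            _rbm.init_rbm(prev, size, family, rng, weight_scale=weight_scale, dtype=dtype)
        )
        prev = size
    head_w = rng.normal(0.0, weight_scale, size=prev).astype(dtype)
    return DbnModel(layers=tuple(layers), head_weights=head_w, head_bias=0.0)


def pretrain_dbn(
    data: np.ndarray,
    layer_sizes: list[int],
    cfg: CdConfig,
    rng: np.random.Generator,
    input_family: str = GAUSSIAN,
    sparsity_layers: tuple[int, ...] = (0,),
    sample_hidden: bool = False,
    rescale: bool = False,
    dtype=np.float64,
) -> DbnModel:
    """Greedy unsupervised pretraining of the stack.

    The first RBM is trained on the raw data; each subsequent RBM is
    trained on the hidden representation of its trained predecessor —
    mean-field probabilities by default, Bernoulli samples when
    ``sample_hidden`` is set. The sparsity penalty of ``cfg`` is applied
    only to the layer indices in ``sparsity_layers``. Labels are never
    consulted.

    With ``rescale`` each layer's input representation is standardized
    per dimension before CD and the affine map is absorbed back into the
    layer (see ``rbm.absorb_input_affine``), so the returned model's
    forward pass needs no external scaling. This keeps activation
    variance alive through deep stacks under short training schedules;
    rescaled layers use Gaussian visible units.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] < 1:
        raise InvalidInputError("pretraining needs at least one sample")
    if rescale:
        input_family = GAUSSIAN
    model = init_dbn(x.shape[1], layer_sizes, rng, input_family=input_family, dtype=dtype)
    layers = []
    rep = x
    for idx, layer in enumerate(model.layers):
        layer_cfg = cfg if idx in sparsity_layers else replace(cfg, sparsity_weight=0.0)
        if rescale:
            layer = replace(layer, visible_family=GAUSSIAN)
            mu, sd = rep.mean(axis=0), rep.std(axis=0)
            sd = np.where(sd < 1e-8, 1.0, sd)
            trained = _rbm.train_rbm((rep - mu) / sd, layer, layer_cfg, rng)
            trained = _rbm.absorb_input_affine(trained, mu, sd)
            # temper saturated units: a hidden unit whose pre-activation
            # spread is far beyond the sigmoid's linear range quantizes
            # its input and blocks fine-tuning gradients
            pre = (rep @ trained.weights) / (
                trained.sigma**2 if trained.visible_family == GAUSSIAN else 1.0
            ) + trained.hidden_bias
            scale = np.minimum(1.0, 1.5 / np.maximum(pre.std(axis=0), 1e-8))
            trained = replace(
                trained,
                weights=trained.weights * scale,
                hidden_bias=trained.hidden_bias * scale,
            )
        else:
            trained = _rbm.train_rbm(rep, layer, layer_cfg, rng)
        layers.append(trained)
        probs = _rbm.hidden_conditional(rep, trained)
        if sample_hidden:
            rep = (rng.uniform(size=probs.shape) < probs).astype(float)
        else:
            rep = probs
    return replace(model, layers=tuple(layers))


def _layer_scale(layer: RbmParams) -> float:
    return layer.sigma**2 if layer.visible_family == GAUSSIAN else 1.0


def dbn_forward_batch(model: DbnModel, x: np.ndarray):
    """Mean-field forward pass for a (batch, n_input) matrix.

    Returns ``(activations, probs)`` where activations is the list
    ``[x, a_1, ..., a_L]`` of layer outputs and probs the (batch,) vector
    of head sigmoid outputs.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_input:
        raise DimensionMismatchError(
            f"input dimension {x.shape[1]} != {model.n_input}"
        )
    acts = [x]
    for layer in model.layers:
        acts.append(_rbm.hidden_conditional(acts[-1], layer))
    probs = _sigmoid(acts[-1] @ model.head_weights + model.head_bias)
    return acts, probs


def dbn_forward(model: DbnModel, x: np.ndarray):
    """Single-vector forward pass: (per-layer activations, output probability)."""
    acts, probs = dbn_forward_batch(model, np.asarray(x, dtype=float)[None, :])
    return [a[0] for a in acts[1:]], float(probs[0])


def dbn_backward(
    model: DbnModel,
    acts: list[np.ndarray],
    probs: np.ndarray,
    d_logit: np.ndarray | None = None,
    d_top: np.ndarray | None = None,
):
    """Backpropagate through head and layers.

    ``d_logit`` is dL/d(head pre-activation), shape (batch,); ``d_top`` is
    an additional gradient on the top-layer activation, shape
    (batch, top_dim) — used when the top activation also feeds a fusion
    head. Returns ``(grads, d_input)`` with grads keyed ``w{i}``/``b{i}``
    per layer plus ``head_w``/``head_b``.
    """
    top = acts[-1]
    grads: dict[str, np.ndarray] = {}
    if d_logit is None:
        d_logit = np.zeros(top.shape[0])
    d_logit = np.asarray(d_logit, dtype=float)
    grads["head_w"] = top.T @ d_logit
    grads["head_b"] = float(np.sum(d_logit))
    d_act = np.outer(d_logit, model.head_weights)
    if d_top is not None:
        d_act = d_act + d_top
    for idx in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[idx]
        a_out, a_in = acts[idx + 1], acts[idx]
        d_pre = d_act * a_out * (1.0 - a_out)
        scale = _layer_scale(layer)
        grads[f"w{idx}"] = a_in.T @ d_pre / scale
        grads[f"b{idx}"] = d_pre.sum(axis=0)
        d_act = d_pre @ layer.weights.T / scale
    return grads, d_act


def dbn_loss_and_grads(model: DbnModel, x: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradients (backprop path)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    acts, probs = dbn_forward_batch(model, x)
    eps = 1e-12
    p = np.clip(probs, eps, 1.0 - eps)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    d_logit = (probs - y) / x.shape[0]
    grads, _ = dbn_backward(model, acts, probs, d_logit)
    return loss, grads


def _apply_grads(model: DbnModel, grads, velocity, lr: float, momentum: float):
    if velocity is None:
        velocity = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in grads.items()}
    new_vel = {
        k: momentum * velocity[k] - np.asarray(grads[k], dtype=float) for k in grads
    }
    layers = []
    for idx, layer in enumerate(model.layers):
        layers.append(
            replace(
                layer,
                weights=layer.weights + lr * new_vel[f"w{idx}"],
                hidden_bias=layer.hidden_bias + lr * new_vel[f"b{idx}"],
            )
        )
    model = replace(
        model,
        layers=tuple(layers),
        head_weights=model.head_weights + lr * new_vel["head_w"],
        head_bias=model.head_bias + lr * new_vel["head_b"],
    )
    return model, new_vel


def fine_tune(
    model: DbnModel,
    data: np.ndarray,
    labels: np.ndarray,
    cfg: FineTuneConfig,
    rng: np.random.Generator,
) -> DbnModel:
    """Discriminative fine-tuning by minibatch SGD on binary cross-entropy.

    Layer dimensions are never altered; only weights, biases and the head
    move. Returns a new model; the input model is unchanged.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    y = np.asarray(labels, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise InvalidInputError("data and labels disagree in length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InvalidInputError("labels must be binary")
    if len(np.unique(y)) < 2:
        warnings.warn("fine_tune received a single-class label vector", stacklevel=2)
    velocity = None
    for _ in range(cfg.epochs):
        order = rng.permutation(x.shape[0])
        for start in range(0, x.shape[0], cfg.minibatch_size):
            sel = order[start : start + cfg.minibatch_size]
            _, grads = dbn_loss_and_grads(model, x[sel], y[sel])
            if cfg.weight_decay > 0:
                for idx, layer in enumerate(model.layers):
                    grads[f"w{idx}"] = grads[f"w{idx}"] + cfg.weight_decay * layer.weights
                grads["head_w"] = grads["head_w"] + cfg.weight_decay * model.head_weights
            model, velocity = _apply_grads(
                model, grads, velocity, cfg.learning_rate, cfg.momentum
            )
    return model
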