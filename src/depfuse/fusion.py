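"""Logit-level fusion and joint fine-tuning of the two streams.

The standalone streams emit session probabilities p_2D (mean of per-frame,
per-channel sigmoid outputs) and p_3D (LSTM head on the final hidden
state). Fusion combines them two ways:

* **Logit sum** (the default inference rule):
  y_2D-3D = sigmoid(logit(p_2D) + logit(p_3D)).
* **Joint head**: a fully connected sigmoid unit over the concatenated
  top features (502-d fused channel activation sum ++ 64-d final LSTM
  hidden state); its cross-entropy is the third term of the joint loss.

Joint fine-tuning minimizes

    L = lambda1 * L_2D + lambda2 * L_3D + lambda3 * L_2D-3D

with lambda = (1, 1, 0.1) by default; gradients flow into both streams and
the joint head.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import dbn as _dbn
from . import lstm as _lstm
from .architectures import Dgdn3D, Sadn2D
from .dbn import FineTuneConfig
from .errors import ConfigurationError, DimensionMismatchError, InvalidInputError
from .lstm import LstmState
from .rbm import _sigmoid

__all__ = [
    "FusionConfig",
    "JointNetwork",
    "SessionFeatures",
    "cross_entropy",
    "logit",
    "fused_probability",
    "fused_loss",
    "joint_forward",
    "predict",
    "fit_joint",
    "fit_stream3d",
]

logger = logging.getLogger(__name__)
EPS = 1e-12


@dataclass(frozen=True)
class FusionConfig:
    """Weights of the three loss terms (defaults 1, 1, 0.1)."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 0.1

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ConfigurationError("loss weights must be nonnegative")


@dataclass(frozen=True)
class SessionFeatures:
    """Preprocessed inputs of one session.

    channels: (3, T, image_dim) flattened per-channel frame vectors;
    frames3d: (T, 3*n_landmarks) normalized landmark vectors;
    aus: (T, n_aus) normalized AU intensities; label in {0, 1}.
    """

    channels: np.ndarray
    frames3d: np.ndarray
    aus: np.ndarray
    label: int

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        f3 = np.atleast_2d(np.asarray(self.frames3d, dtype=float))
        au = np.atleast_2d(np.asarray(self.aus, dtype=float))
        if ch.ndim != 3 or ch.shape[0] != 3:
            raise DimensionMismatchError("channels must be (3, T, image_dim)")
        if not ch.shape[1] == f3.shape[0] == au.shape[0]:
            raise InvalidInputError("2D and 3D streams are not aligned in time")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "frames3d", f3)
        object.__setattr__(self, "aus", au)


@dataclass(frozen=True)
class JointNetwork:
    """Both streams plus the fully connected fusion head."""

    sadn: Sadn2D
    dgdn: Dgdn3D
    joint_weights: np.ndarray
    joint_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.dgdn.variant != "au-4dbn-lstm":
            raise ConfigurationError("joint training expects the au-4dbn-lstm 3D stream")
        jw = np.asarray(self.joint_weights, dtype=float)
        want = self.sadn.feature_dim + self.dgdn.feature_dim
        if jw.shape != (want,):
            raise ConfigurationError(
                f"joint head length {jw.shape} != concatenated feature dim ({want},)"
            )
        object.__setattr__(self, "joint_weights", jw)


def init_joint(sadn: Sadn2D, dgdn: Dgdn3D, rng: np.random.Generator) -> JointNetwork:
    w = rng.normal(0.0, 0.01, size=sadn.feature_dim + dgdn.feature_dim)
    return JointNetwork(sadn=sadn, dgdn=dgdn, joint_weights=w, joint_bias=0.0)


# ---------------------------------------------------------------------------
# elementary fusion operations


def cross_entropy(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Summed binary cross-entropy -sum[y log p + (1-y) log(1-p)].

    Probabilities exactly at 0 or 1 are clamped to EPS and logged.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != p.shape:
        raise DimensionMismatchError("label and probability vectors differ in length")
    if np.any((p <= 0.0) | (p >= 1.0)):
        if np.any((p < 0.0) | (p > 1.0)):
            raise InvalidInputError("probabilities must lie in [0, 1]")
        logger.warning("cross_entropy: clamping %d saturated probabilities", int(np.sum((p == 0) | (p == 1))))
        p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def logit(p) -> float | np.ndarray:
    """Log-odds log(p / (1-p)); inverse of the sigmoid."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise InvalidInputError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def fused_probability(p2d: float, p3d: float) -> float:
    """sigmoid(logit(p2d) + logit(p3d)) — the logit-sum fusion rule."""
    return float(_sigmoid(logit(p2d) + logit(p3d)))


# ---------------------------------------------------------------------------
# joint forward / backward


def _clip(p: np.ndarray | float):
    return np.clip(p, EPS, 1.0 - EPS)


def joint_forward(net: JointNetwork, sess: SessionFeatures, aggregate2d: str = "mean-frame"):
    """Forward both streams and the fusion head for one session.

    ``aggregate2d`` selects how the appearance stream summarizes the
    session: ``"mean-frame"`` scores the temporal-mean channel vectors,
    ``"mean-prob"`` averages per-frame scores. Returns a cache dict
    holding per-stream activations and the three probabilities p2d, p3d,
    p23 (joint-head) plus p_fused (logit-sum).
    """
    T = sess.frames3d.shape[0]
    ch_acts, ch_probs = [], []
    if aggregate2d == "mean-frame":
        # static appearance: the session's temporal-mean frame per channel
        for c in range(3):
            x2 = sess.channels[c].mean(axis=0)[None, :]
            acts, probs = _dbn.dbn_forward_batch(net.sadn.channel_models[c], x2)
            ch_acts.append(acts)
            ch_probs.append(probs)
        p2d = float(np.mean(ch_probs))
        fused_feat = sum(acts[-1][0] for acts in ch_acts)
    else:
        # per-frame scoring averaged over the session
        for c in range(3):
            acts, probs = _dbn.dbn_forward_batch(net.sadn.channel_models[c], sess.channels[c])
            ch_acts.append(acts)
            ch_probs.append(probs)
        p2d = float(np.mean(ch_probs))
        fused_feat = sum(acts[-1].mean(axis=0) for acts in ch_acts)

    dg = net.dgdn
    base_acts, _ = _dbn.dbn_forward_batch(dg.base_dbn, sess.frames3d)
    concat = np.concatenate([base_acts[-1], sess.aus], axis=1)
    s2 = dg.top_rbm.sigma**2
    feats = _sigmoid((concat @ dg.top_rbm.weights) / s2 + dg.top_rbm.hidden_bias)
    outputs, _, lstm_caches = _lstm.lstm_forward_cached(feats, dg.lstm)
    h_final = outputs[-1]
    p3d = float(_sigmoid(h_final @ dg.lstm_head_weights + dg.lstm_head_bias))

    z = np.concatenate([fused_feat, h_final])
    p23 = float(_sigmoid(z @ net.joint_weights + net.joint_bias))
    p_fused = float(_sigmoid(logit(_clip(p2d)) + logit(_clip(p3d))))
    return {
        "T": T,
        "ch_acts": ch_acts,
        "ch_probs": ch_probs,
        "p2d": p2d,
        "fused_feat": fused_feat,
        "base_acts": base_acts,
        "concat": concat,
        "feats": feats,
        "outputs": outputs,
        "lstm_caches": lstm_caches,
        "h_final": h_final,
        "p3d": p3d,
        "z": z,
        "p23": p23,
        "p_fused": p_fused,
    }


def joint_param_arrays(net: JointNetwork) -> dict[str, np.ndarray]:
    """Parameter arrays keyed like the gradient dicts (weights the
    optimizer moves; visible biases are excluded)."""
    p: dict[str, np.ndarray] = {}
    for c, model in enumerate(net.sadn.channel_models):
        for i, layer in enumerate(model.layers):
            p[f"ch{c}.w{i}"] = layer.weights
            p[f"ch{c}.b{i}"] = layer.hidden_bias
        p[f"ch{c}.head_w"] = model.head_weights
        p[f"ch{c}.head_b"] = np.asarray(model.head_bias)
    dg = net.dgdn
    for i, layer in enumerate(dg.base_dbn.layers):
        p[f"base.w{i}"] = layer.weights
        p[f"base.b{i}"] = layer.hidden_bias
    p["top.w"] = dg.top_rbm.weights
    p["top.b"] = dg.top_rbm.hidden_bias
    for li, lp in enumerate(dg.lstm.layers):
        for name in lp.__dataclass_fields__:
            p[f"lstm{li}.{name}"] = getattr(lp, name)
    p["head3d.w"] = dg.lstm_head_weights
    p["head3d.b"] = np.asarray(dg.lstm_head_bias)
    p["joint.w"] = net.joint_weights
    p["joint.b"] = np.asarray(net.joint_bias)
    return p


def _is_weight_key(key: str) -> bool:
    tail = key.rsplit(".", 1)[-1]
    return tail.startswith("w") or tail == "head_w"


def _zero_grads(net: JointNetwork) -> dict[str, np.ndarray]:
    g: dict[str, np.ndarray] = {}
    for c, model in enumerate(net.sadn.channel_models):
        for i, layer in enumerate(model.layers):
            g[f"ch{c}.w{i}"] = np.zeros_like(layer.weights)
            g[f"ch{c}.b{i}"] = np.zeros_like(layer.hidden_bias)
        g[f"ch{c}.head_w"] = np.zeros_like(model.head_weights)
        g[f"ch{c}.head_b"] = np.zeros(())
    dg = net.dgdn
    for i, layer in enumerate(dg.base_dbn.layers):
        g[f"base.w{i}"] = np.zeros_like(layer.weights)
        g[f"base.b{i}"] = np.zeros_like(layer.hidden_bias)
    g["top.w"] = np.zeros_like(dg.top_rbm.weights)
    g["top.b"] = np.zeros_like(dg.top_rbm.hidden_bias)
    for li, lp in enumerate(dg.lstm.layers):
        for name in lp.__dataclass_fields__:
            g[f"lstm{li}.{name}"] = np.zeros_like(getattr(lp, name))
    g["head3d.w"] = np.zeros_like(dg.lstm_head_weights)
    g["head3d.b"] = np.zeros(())
    g["joint.w"] = np.zeros_like(net.joint_weights)
    g["joint.b"] = np.zeros(())
    return g


def fused_loss(
    batch: list[SessionFeatures],
    net: JointNetwork,
    cfg: FusionConfig = FusionConfig(),
    train_base: bool = True,
    aggregate2d: str = "mean-frame",
):
    """Mean joint loss over a batch of sessions, with gradients.

    Returns ``(loss, grads)``; grads keys follow the naming of
    ``_zero_grads``. ``train_base=False`` skips backpropagation into the
    3D base DBN (its gradients stay zero), which the stream trainers use
    for speed.
    """
    if not batch:
        raise InvalidInputError("empty batch")
    grads = _zero_grads(net)
    total = 0.0
    B = len(batch)
    dg = net.dgdn
    s2_top = dg.top_rbm.sigma**2
    # sessions of equal length are processed as one stacked batch
    groups: dict[int, list[int]] = {}
    for i, sess in enumerate(batch):
        groups.setdefault(sess.frames3d.shape[0], []).append(i)
    for T, idxs in groups.items():
        sub = [batch[i] for i in idxs]
        nb = len(sub)
        y = np.array([float(s.label) for s in sub])

        # ---- forward, 2D
        mean_frame = aggregate2d == "mean-frame"
        ch_acts, ch_probs = [], []
        for c in range(3):
            if mean_frame:
                x = np.stack([s.channels[c].mean(axis=0) for s in sub])  # (nb, D)
            else:
                x = np.concatenate([s.channels[c] for s in sub])  # (nb*T, D)
            acts, probs = _dbn.dbn_forward_batch(net.sadn.channel_models[c], x)
            ch_acts.append(acts)
            ch_probs.append(probs if mean_frame else probs.reshape(nb, T))
        F2 = net.sadn.feature_dim
        if mean_frame:
            p2d = _clip(np.mean(ch_probs, axis=0))
            fused_feat = sum(a[-1] for a in ch_acts)
        else:
            p2d = _clip(np.mean([p.mean(axis=1) for p in ch_probs], axis=0))
            fused_feat = sum(a[-1].reshape(nb, T, F2).mean(axis=1) for a in ch_acts)

        # ---- forward, 3D
        f3 = np.concatenate([s.frames3d for s in sub])  # (nb*T, L)
        aus = np.stack([s.aus for s in sub])  # (nb, T, A)
        base_acts, _ = _dbn.dbn_forward_batch(dg.base_dbn, f3)
        concat = np.concatenate(
            [base_acts[-1].reshape(nb, T, -1), aus], axis=2
        )  # (nb, T, C)
        feats = _sigmoid(
            (concat @ dg.top_rbm.weights) / s2_top + dg.top_rbm.hidden_bias
        )  # (nb, T, H)
        outputs, _, lstm_caches = _lstm.lstm_forward_cached(
            feats.transpose(1, 0, 2), dg.lstm
        )  # (T, nb, U)
        h_final = outputs[-1]
        p3d = _clip(_sigmoid(h_final @ dg.lstm_head_weights + dg.lstm_head_bias))

        # ---- fusion head
        z = np.concatenate([fused_feat, h_final], axis=1)
        p23 = _clip(_sigmoid(z @ net.joint_weights + net.joint_bias))
        total += (
            cfg.lambda1 * cross_entropy(y, p2d)
            + cfg.lambda2 * cross_entropy(y, p3d)
            + cfg.lambda3 * cross_entropy(y, p23)
        )

        # ---- backward: joint head
        d23 = cfg.lambda3 * (p23 - y) / B  # (nb,)
        grads["joint.w"] += z.T @ d23
        grads["joint.b"] += d23.sum()
        d_z = np.outer(d23, net.joint_weights)
        d_fused = d_z[:, :F2]
        d_hT_joint = d_z[:, F2:]

        # ---- backward: 2D stream (p2d is a mean of channel sigmoid outputs)
        dL_dp2d = cfg.lambda1 * (p2d - y) / (p2d * (1.0 - p2d)) / B
        for c in range(3):
            probs = ch_probs[c]
            if mean_frame:
                d_logit = dL_dp2d * probs * (1.0 - probs) / 3.0
                d_top = d_fused
            else:
                d_logit = (dL_dp2d[:, None] * probs * (1.0 - probs) / (3.0 * T)).ravel()
                d_top = np.repeat(d_fused / T, T, axis=0)
                probs = probs.ravel()
            ch_grads, _ = _dbn.dbn_backward(
                net.sadn.channel_models[c], ch_acts[c], probs, d_logit, d_top
            )
            for k, v in ch_grads.items():
                grads[f"ch{c}.{k}"] += v

        # ---- backward: 3D stream
        d3 = cfg.lambda2 * (p3d - y) / B
        grads["head3d.w"] += h_final.T @ d3
        grads["head3d.b"] += d3.sum()
        d_hT = np.outer(d3, dg.lstm_head_weights) + d_hT_joint
        d_outputs = np.zeros_like(outputs)
        d_outputs[-1] = d_hT
        lstm_grads, d_feats = _lstm.lstm_backprop(dg.lstm, lstm_caches, d_outputs)
        for li, gdict in enumerate(lstm_grads):
            for name, v in gdict.items():
                grads[f"lstm{li}.{name}"] += v
        d_feats = d_feats.transpose(1, 0, 2)  # (nb, T, H)
        d_pre_top = (d_feats * feats * (1.0 - feats)).reshape(nb * T, -1)
        concat_flat = concat.reshape(nb * T, -1)
        grads["top.w"] += concat_flat.T @ d_pre_top / s2_top
        grads["top.b"] += d_pre_top.sum(axis=0)
        if train_base:
            d_concat = d_pre_top @ dg.top_rbm.weights.T / s2_top
            d_base_top = d_concat[:, : dg.base_dbn.top_dim]
            base_grads, _ = _dbn.dbn_backward(
                dg.base_dbn, base_acts, None, None, d_base_top
            )
            for i in range(len(dg.base_dbn.layers)):
                grads[f"base.w{i}"] += base_grads[f"w{i}"]
                grads[f"base.b{i}"] += base_grads[f"b{i}"]
    return total / B, grads


def predict(net: JointNetwork, sess: SessionFeatures, rule: str = "logit-sum") -> int:
    """Binary decision for one session; class 1 iff the fused output >= 0.5."""
    cache = joint_forward(net, sess)
    p = cache["p_fused"] if rule == "logit-sum" else cache["p23"]
    return int(p >= 0.5)


# ---------------------------------------------------------------------------
# SGD drivers


def _apply(net: JointNetwork, grads, velocity, lr: float, momentum: float, freeze=()):
    def frozen(key: str) -> bool:
        return any(key.startswith(p) for p in freeze)

    if velocity is None:
        velocity = {k: np.zeros_like(v) for k, v in grads.items()}
    vel = {
        k: (momentum * velocity[k] - grads[k]) if not frozen(k) else velocity[k]
        for k in grads
    }

    def upd(key, arr):
        if frozen(key):
            return arr
        return arr + lr * vel[key]

    channels = []
    for c, model in enumerate(net.sadn.channel_models):
        layers = tuple(
            replace(
                layer,
                weights=upd(f"ch{c}.w{i}", layer.weights),
                hidden_bias=upd(f"ch{c}.b{i}", layer.hidden_bias),
            )
            for i, layer in enumerate(model.layers)
        )
        channels.append(
            replace(
                model,
                layers=layers,
                head_weights=upd(f"ch{c}.head_w", model.head_weights),
                head_bias=float(upd(f"ch{c}.head_b", np.asarray(model.head_bias))),
            )
        )
    dg = net.dgdn
    base_layers = tuple(
        replace(
            layer,
            weights=upd(f"base.w{i}", layer.weights),
            hidden_bias=upd(f"base.b{i}", layer.hidden_bias),
        )
        for i, layer in enumerate(dg.base_dbn.layers)
    )
    lstm_layers = tuple(
        replace(
            lp,
            **{
                name: upd(f"lstm{li}.{name}", getattr(lp, name))
                for name in lp.__dataclass_fields__
            },
        )
        for li, lp in enumerate(dg.lstm.layers)
    )
    dgdn = replace(
        dg,
        base_dbn=replace(dg.base_dbn, layers=base_layers),
        top_rbm=replace(
            dg.top_rbm,
            weights=upd("top.w", dg.top_rbm.weights),
            hidden_bias=upd("top.b", dg.top_rbm.hidden_bias),
        ),
        lstm=replace(dg.lstm, layers=lstm_layers),
        lstm_head_weights=upd("head3d.w", dg.lstm_head_weights),
        lstm_head_bias=float(upd("head3d.b", np.asarray(dg.lstm_head_bias))),
    )
    net = replace(
        net,
        sadn=Sadn2D(channel_models=tuple(channels)),
        dgdn=dgdn,
        joint_weights=upd("joint.w", net.joint_weights),
        joint_bias=float(upd("joint.b", np.asarray(net.joint_bias))),
    )
    return net, vel


def fit_joint(
    net: JointNetwork,
    sessions: list[SessionFeatures],
    cfg: FusionConfig,
    opt: FineTuneConfig,
    rng: np.random.Generator,
    freeze: tuple[str, ...] = (),
    train_base: bool = True,
    aggregate2d: str = "mean-frame",
):
    """Joint fine-tuning of both streams and the fusion head.

    Minibatch SGD with momentum on the weighted three-term loss. ``freeze``
    holds parameter-key prefixes excluded from updates. Returns
    (trained network, per-epoch mean loss history).
    """
    velocity = None
    history = []
    idx = np.arange(len(sessions))
    for _ in range(opt.epochs):
        rng.shuffle(idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(sessions), opt.minibatch_size):
            batch = [sessions[i] for i in idx[start : start + opt.minibatch_size]]
            loss, grads = fused_loss(
                batch, net, cfg, train_base=train_base, aggregate2d=aggregate2d
            )
            if opt.weight_decay > 0:
                params = joint_param_arrays(net)
                for k in grads:
                    if _is_weight_key(k):
                        grads[k] = grads[k] + opt.weight_decay * params[k]
            net, velocity = _apply(net, grads, velocity, opt.learning_rate, opt.momentum, freeze)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    return net, history


def fit_stream3d(
    dgdn: Dgdn3D,
    concat_list: list[np.ndarray],
    labels: np.ndarray,
    opt: FineTuneConfig,
    rng: np.random.Generator,
):
    """Supervised training of the 3D head stack with the base DBN frozen.

    ``concat_list`` holds, per session, the (T, 1024 + n_aus) matrices of
    base-DBN top activations concatenated with AU intensities (computed
    once since the base is frozen). Trains the top RBM weights (as a
    feedforward layer), the LSTM and its head by BPTT.
    """
    s2 = dgdn.top_rbm.sigma**2
    vel: dict[str, np.ndarray] | None = None
    y = np.asarray(labels, dtype=float)
    idx = np.arange(len(concat_list))
    lengths = {c.shape[0] for c in concat_list}
    stacked = np.stack(concat_list) if len(lengths) == 1 else None
    for _ in range(opt.epochs):
        rng.shuffle(idx)
        for start in range(0, len(idx), opt.minibatch_size):
            sel = idx[start : start + opt.minibatch_size]
            grads = {
                "top.w": np.zeros_like(dgdn.top_rbm.weights),
                "top.b": np.zeros_like(dgdn.top_rbm.hidden_bias),
                "head3d.w": np.zeros_like(dgdn.lstm_head_weights),
                "head3d.b": np.zeros(()),
            }
            for li, lp in enumerate(dgdn.lstm.layers):
                for name in lp.__dataclass_fields__:
                    grads[f"lstm{li}.{name}"] = np.zeros_like(getattr(lp, name))
            B = len(sel)
            concat = (
                stacked[sel]
                if stacked is not None
                else np.stack([concat_list[i] for i in sel])
            )  # (B, T, C)
            feats = _sigmoid((concat @ dgdn.top_rbm.weights) / s2 + dgdn.top_rbm.hidden_bias)
            outputs, _, caches = _lstm.lstm_forward_cached(
                feats.transpose(1, 0, 2), dgdn.lstm
            )
            h_final = outputs[-1]  # (B, U)
            p = _clip(_sigmoid(h_final @ dgdn.lstm_head_weights + dgdn.lstm_head_bias))
            d = (p - y[sel]) / B
            grads["head3d.w"] += h_final.T @ d
            grads["head3d.b"] += d.sum()
            d_outputs = np.zeros_like(outputs)
            d_outputs[-1] = np.outer(d, dgdn.lstm_head_weights)
            lstm_grads, d_feats = _lstm.lstm_backprop(dgdn.lstm, caches, d_outputs)
            for li, gdict in enumerate(lstm_grads):
                for name, v in gdict.items():
                    grads[f"lstm{li}.{name}"] += v
            d_pre = (d_feats.transpose(1, 0, 2) * feats * (1.0 - feats)).reshape(
                -1, feats.shape[-1]
            )
            concat_flat = concat.reshape(-1, concat.shape[-1])
            grads["top.w"] += concat_flat.T @ d_pre / s2
            grads["top.b"] += d_pre.sum(axis=0)
            if vel is None:
                vel = {k: np.zeros_like(v) for k, v in grads.items()}
            if opt.weight_decay > 0:
                grads["top.w"] = grads["top.w"] + opt.weight_decay * dgdn.top_rbm.weights
                grads["head3d.w"] = grads["head3d.w"] + opt.weight_decay * dgdn.lstm_head_weights
                for li, lp in enumerate(dgdn.lstm.layers):
                    for name in lp.__dataclass_fields__:
                        if name.startswith("w"):
                            grads[f"lstm{li}.{name}"] = (
                                grads[f"lstm{li}.{name}"] + opt.weight_decay * getattr(lp, name)
                            )
            vel = {k: opt.momentum * vel[k] - grads[k] for k in grads}
            lstm_layers = tuple(
                replace(
                    lp,
                    **{
                        name: getattr(lp, name) + opt.learning_rate * vel[f"lstm{li}.{name}"]
                        for name in lp.__dataclass_fields__
                    },
                )
                for li, lp in enumerate(dgdn.lstm.layers)
            )
            dgdn = replace(
                dgdn,
                top_rbm=replace(
                    dgdn.top_rbm,
                    weights=dgdn.top_rbm.weights + opt.learning_rate * vel["top.w"],
                    hidden_bias=dgdn.top_rbm.hidden_bias + opt.learning_rate * vel["top.b"],
                ),
                lstm=replace(dgdn.lstm, layers=lstm_layers),
                lstm_head_weights=dgdn.lstm_head_weights + opt.learning_rate * vel["head3d.w"],
                lstm_head_bias=float(dgdn.lstm_head_bias + opt.learning_rate * vel["head3d.b"]),
            )
    return dgdn
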