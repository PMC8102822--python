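"""Stacked LSTM implemented from first principles.

Gate equations for one layer at step t (x input, h hidden, C cell):

    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)
    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)
    g_t = tanh   (W_xg x_t + W_hg h_{t-1} + b_g)
    C_t = C_{t-1} * f_t + i_t * g_t
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)
    h_t = o_t * tanh(C_t)

Two layers (200 then 64 units by default) are stacked: the hidden sequence
of the first feeds the second. Hidden and cell state can be carried across
minibatch chunks ("stateful" training); gradients are truncated at chunk
boundaries. Backpropagation through time covers all twelve weight matrices
and four biases per layer and also yields input gradients so upstream
networks can be trained jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DimensionMismatchError, InvalidInputError

__all__ = [
    "LstmLayerParams",
    "LstmParams",
    "LstmState",
    "init_lstm",
    "zero_state",
    "lstm_step",
    "lstm_run",
    "lstm_forward_cached",
    "lstm_backprop",
]

GATES = ("f", "i", "g", "o")

_sigmoid = lambda z: 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass(frozen=True)
class LstmLayerParams:
    """Per-gate weights of one LSTM layer: W_x* (input, units), W_h* (units, units), b_* (units,)."""

    w_xf: np.ndarray
    w_hf: np.ndarray
    b_f: np.ndarray
    w_xi: np.ndarray
    w_hi: np.ndarray
    b_i: np.ndarray
    w_xg: np.ndarray
    w_hg: np.ndarray
    b_g: np.ndarray
    w_xo: np.ndarray
    w_ho: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        d, u = self.w_xf.shape
        for g in GATES:
            if getattr(self, f"w_x{g}").shape != (d, u):
                raise ConfigurationError("input weight shapes differ across gates")
            if getattr(self, f"w_h{g}").shape != (u, u):
                raise ConfigurationError("recurrent weights must be (units, units)")
            if getattr(self, f"b_{g}").shape != (u,):
                raise ConfigurationError("bias length must equal units")

    @property
    def input_dim(self) -> int:
        return self.w_xf.shape[0]

    @property
    def units(self) -> int:
        return self.w_xf.shape[1]


@dataclass(frozen=True)
class LstmParams:
    """Stack of LSTM layers; layer l+1 consumes the hidden sequence of layer l."""

    layers: tuple[LstmLayerParams, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("need at least one LSTM layer")
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.units != upper.input_dim:
                raise ConfigurationError("stacked layer dimensions do not chain")

    @property
    def input_dim(self) -> int:
        return self.layers[0].input_dim

    @property
    def units(self) -> list[int]:
        return [l.units for l in self.layers]


@dataclass
class LstmState:
    """(hidden, cell) vectors per layer."""

    hidden: list[np.ndarray]
    cell: list[np.ndarray]

    def copy(self) -> "LstmState":
        return LstmState([h.copy() for h in self.hidden], [c.copy() for c in self.cell])


def init_lstm(
    input_dim: int,
    units: list[int] = (200, 64),
    rng: np.random.Generator | None = None,
    weight_scale: float = 0.1,
) -> LstmParams:
    """Random N(0, weight_scale) weights, zero biases."""
    rng = np.random.default_rng(rng)
    layers = []
    prev = input_dim
    for u in units:
        kw = {}
        for g in GATES:
            kw[f"w_x{g}"] = rng.normal(0.0, weight_scale, size=(prev, u))
            kw[f"w_h{g}"] = rng.normal(0.0, weight_scale, size=(u, u))
            kw[f"b_{g}"] = np.zeros(u)
        layers.append(LstmLayerParams(**kw))
        prev = u
    return LstmParams(layers=tuple(layers))


def zero_state(params: LstmParams) -> LstmState:
    return LstmState(
        hidden=[np.zeros(u) for u in params.units],
        cell=[np.zeros(u) for u in params.units],
    )


def _layer_step(x, h_prev, c_prev, p: LstmLayerParams):
    f = _sigmoid(x @ p.w_xf + h_prev @ p.w_hf + p.b_f)
    i = _sigmoid(x @ p.w_xi + h_prev @ p.w_hi + p.b_i)
    g = np.tanh(x @ p.w_xg + h_prev @ p.w_hg + p.b_g)
    c = c_prev * f + i * g
    o = _sigmoid(x @ p.w_xo + h_prev @ p.w_ho + p.b_o)
    tc = np.tanh(c)
    h = o * tc
    cache = (x, h_prev, c_prev, f, i, g, o, c, tc)
    return h, c, cache


def lstm_step(x: np.ndarray, state: LstmState, params: LstmParams) -> LstmState:
    """Advance the whole stack by one time step; input of layer l>0 is h of layer l-1."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.input_dim,):
        raise DimensionMismatchError(
            f"input shape {x.shape} != ({params.input_dim},)"
        )
    hidden, cell = [], []
    inp = x
    for layer, h_prev, c_prev in zip(params.layers, state.hidden, state.cell):
        h, c, _ = _layer_step(inp, h_prev, c_prev, layer)
        hidden.append(h)
        cell.append(c)
        inp = h
    return LstmState(hidden=hidden, cell=cell)


def lstm_forward_cached(
    sequence: np.ndarray,
    params: LstmParams,
    initial: LstmState | None = None,
):
    """Forward pass with per-step caches for BPTT.

    ``sequence`` is (T, input_dim) for a single sequence or
    (T, batch, input_dim) for a batch run in lockstep. Returns
    (outputs (T[, batch], top_units), final state, caches); caches is a
    per-layer list of per-step gate caches.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim == 1:
        seq = seq[:, None]
    single = seq.ndim == 2
    if single:
        seq = seq[:, None, :]
    if seq.shape[0] == 0:
        raise InvalidInputError("empty sequence")
    if seq.shape[2] != params.input_dim:
        raise DimensionMismatchError(
            f"sequence feature dim {seq.shape[2]} != {params.input_dim}"
        )
    B = seq.shape[1]
    if initial is not None:
        hidden = [np.atleast_2d(np.asarray(h, dtype=float)) for h in initial.hidden]
        cell = [np.atleast_2d(np.asarray(c, dtype=float)) for c in initial.cell]
    else:
        hidden = [np.zeros((B, u)) for u in params.units]
        cell = [np.zeros((B, u)) for u in params.units]
    caches: list[list] = [[] for _ in params.layers]
    layer_inputs = seq
    for li, layer in enumerate(params.layers):
        outs = np.empty((seq.shape[0], B, layer.units))
        h, c = hidden[li], cell[li]
        for t in range(seq.shape[0]):
            h, c, cache = _layer_step(layer_inputs[t], h, c, layer)
            caches[li].append(cache)
            outs[t] = h
        hidden[li], cell[li] = h, c
        layer_inputs = outs
    if single:
        final = LstmState([h[0] for h in hidden], [c[0] for c in cell])
        return layer_inputs[:, 0, :], final, caches
    return layer_inputs, LstmState(hidden, cell), caches


def lstm_run(
    sequence: np.ndarray,
    params: LstmParams,
    initial: LstmState | None = None,
    stateful: bool = False,
):
    """Run the stack over a sequence.

    Returns (outputs, final state). When ``stateful`` the caller feeds the
    returned state into the next chunk; chunked execution is exactly
    equivalent to a single monolithic run. State is re-zeroed by passing
    ``initial=None`` with ``stateful=False`` at sequence-group boundaries.
    """
    outputs, state, _ = lstm_forward_cached(sequence, params, initial)
    return outputs, state


def _zero_layer_grads(p: LstmLayerParams) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(getattr(p, name)) for name in p.__dataclass_fields__}


def lstm_backprop(
    params: LstmParams,
    caches: list[list],
    d_outputs: np.ndarray,
    d_final: LstmState | None = None,
):
    """Backpropagation through time for the whole stack.

    ``d_outputs`` is dL/dh for the *top* layer at every step, shape
    (T, top_units); ``d_final`` optionally adds gradients on the final
    (hidden, cell) state of each layer. Returns (per-layer gradient dicts,
    d_inputs (T, input_dim)).
    """
    T = len(caches[0])
    d_outputs = np.asarray(d_outputs, dtype=float)
    single = d_outputs.ndim == 2
    if single:
        d_outputs = d_outputs[:, None, :]
    B = d_outputs.shape[1]
    if d_outputs.shape != (T, B, params.layers[-1].units):
        raise DimensionMismatchError("d_outputs shape does not match the forward pass")
    grads = []
    d_h_seq = d_outputs
    for li in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[li]
        g = _zero_layer_grads(layer)
        d_x_seq = np.zeros((T, B, layer.input_dim))
        if d_final is not None:
            dh_next = np.atleast_2d(np.asarray(d_final.hidden[li], dtype=float))
            dc_next = np.atleast_2d(np.asarray(d_final.cell[li], dtype=float))
        else:
            dh_next = np.zeros((B, layer.units))
            dc_next = np.zeros((B, layer.units))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, f, i, gt, o, c, tc = caches[li][t]
            dh = d_h_seq[t] + dh_next
            d_pre_o = dh * tc * o * (1.0 - o)
            dc = dh * o * (1.0 - tc**2) + dc_next
            d_pre_f = dc * c_prev * f * (1.0 - f)
            d_pre_i = dc * gt * i * (1.0 - i)
            d_pre_g = dc * i * (1.0 - gt**2)
            for gate, d_pre in zip(GATES, (d_pre_f, d_pre_i, d_pre_g, d_pre_o)):
                g[f"w_x{gate}"] += x.T @ d_pre
                g[f"w_h{gate}"] += h_prev.T @ d_pre
                g[f"b_{gate}"] += d_pre.sum(axis=0)
            d_x_seq[t] = (
                d_pre_f @ layer.w_xf.T
                + d_pre_i @ layer.w_xi.T
                + d_pre_g @ layer.w_xg.T
                + d_pre_o @ layer.w_xo.T
            )
            dh_next = (
                d_pre_f @ layer.w_hf.T
                + d_pre_i @ layer.w_hi.T
                + d_pre_g @ layer.w_hg.T
                + d_pre_o @ layer.w_ho.T
            )
            dc_next = dc * f
        grads.append(g)
        d_h_seq = d_x_seq
    grads.reverse()
    return grads, (d_h_seq[:, 0, :] if single else d_h_seq)
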