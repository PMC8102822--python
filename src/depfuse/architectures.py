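"""Named network architectures of the two-stream recognizer.

Two streams are assembled from the DBN / LSTM primitives:

* **2D-SADN** — three four-layer DBNs, one per R/G/B channel of a flattened
  face image; the standalone prediction is the mean of the three channel
  outputs and the 502-d fused feature is the element-wise sum of the three
  top-layer activations.
* **3D stream variants** over landmark(+AU) frame vectors:
  ``4dbn`` (landmarks only), ``4dbn-au`` (AUs appended to the input),
  ``au-4dbn`` (AUs concatenated onto the penultimate 1024-d activation and
  fed to a top-level 1041-to-150 RBM), and ``au-4dbn-lstm`` — the 3D-DGDN —
  which runs the 150-d per-frame features through a two-layer (200, 64)
  LSTM and scores the session from the final hidden state.

``ArchitectureSpec`` presets: ``full`` reproduces the published layer
widths exactly; ``desk`` scales widths by 1/16 and images to 32 x 32 for
workstation-scale experiments; ``tiny`` is for fast unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dbn as _dbn
from . import lstm as _lstm
from . import rbm as _rbm
from .dbn import DbnModel, FineTuneConfig
from .errors import ConfigurationError, DimensionMismatchError, InvalidInputError
from .lstm import LstmParams
from .rbm import BERNOULLI, GAUSSIAN, CdConfig, RbmParams, _sigmoid

__all__ = [
    "ArchitectureSpec",
    "Sadn2D",
    "Dgdn3D",
    "VARIANTS",
    "build_sadn2d",
    "build_dgdn3d",
    "sadn2d_predict",
    "dgdn3d_forward",
    "depth_sweep",
]

VARIANTS = ("4dbn", "4dbn-au", "au-4dbn", "au-4dbn-lstm")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer-size preset shared by every constructor."""

    image_size: int = 100
    sadn_sizes: tuple[int, ...] = (8192, 4096, 2048, 502)
    dgdn_sizes: tuple[int, ...] = (3000, 2048, 1024, 128)
    top_rbm_hidden: int = 150
    lstm_units: tuple[int, ...] = (200, 64)
    n_landmarks: int = 1347
    n_aus: int = 17

    @property
    def image_dim(self) -> int:
        return self.image_size * self.image_size

    @property
    def landmark_dim(self) -> int:
        return 3 * self.n_landmarks

    @property
    def top_rbm_visible(self) -> int:
        return self.dgdn_sizes[-2] + self.n_aus

    @classmethod
    def full(cls) -> "ArchitectureSpec":
        return cls()

    @classmethod
    def desk(cls) -> "ArchitectureSpec":
        """DBN widths scaled by 1/16 (rounded up), 32 x 32 images.

        The cheap head stack (top RBM, LSTM) is floored at 1/4 scale: a
        1/16 LSTM keeps only four second-layer units, too few to carry
        the range-over-time statistics the sequence head must compute.
        """
        scale = lambda sizes, k: tuple(math.ceil(s / k) for s in sizes)
        return cls(
            image_size=32,
            sadn_sizes=scale((8192, 4096, 2048, 502), 16),
            dgdn_sizes=scale((3000, 2048, 1024, 128), 16),
            top_rbm_hidden=math.ceil(150 / 4),
            lstm_units=scale((200, 64), 4),
        )

    @classmethod
    def tiny(cls) -> "ArchitectureSpec":
        return cls(
            image_size=16,
            sadn_sizes=(24, 12, 8, 6),
            dgdn_sizes=(32, 16, 8, 4),
            top_rbm_hidden=6,
            lstm_units=(6, 3),
        )

    @classmethod
    def preset(cls, name: str) -> "ArchitectureSpec":
        try:
            return {"full": cls.full, "desk": cls.desk, "tiny": cls.tiny}[name]()
        except KeyError:
            raise ConfigurationError(f"unknown preset {name!r}") from None


@dataclass(frozen=True)
class Sadn2D:
    """Three per-channel DBNs with identical layer sizes."""

    channel_models: tuple[DbnModel, DbnModel, DbnModel]

    def __post_init__(self) -> None:
        sizes = {tuple(m.layer_sizes) for m in self.channel_models}
        if len(self.channel_models) != 3 or len(sizes) != 1:
            raise ConfigurationError("2D-SADN needs three channel DBNs of identical sizes")

    @property
    def input_dim(self) -> int:
        return self.channel_models[0].n_input

    @property
    def feature_dim(self) -> int:
        return self.channel_models[0].top_dim


@dataclass(frozen=True)
class Dgdn3D:
    """One 3D-stream variant; unused components are None."""

    variant: str
    base_dbn: DbnModel
    top_rbm: RbmParams | None = None
    top_head_weights: np.ndarray | None = None
    top_head_bias: float = 0.0
    lstm: LstmParams | None = None
    lstm_head_weights: np.ndarray | None = None
    lstm_head_bias: float = 0.0
    n_aus: int = 17

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.variant in ("au-4dbn", "au-4dbn-lstm"):
            if self.top_rbm is None:
                raise ConfigurationError("AU variants need the top-level RBM")
            if self.top_rbm.n_visible != self.base_dbn.top_dim + self.n_aus:
                raise ConfigurationError(
                    "top RBM visible size must be penultimate hidden + AU count"
                )
        if self.variant == "au-4dbn-lstm":
            if self.lstm is None or self.lstm_head_weights is None:
                raise ConfigurationError("LSTM variant needs LSTM params and head")
            if self.lstm.input_dim != self.top_rbm.n_hidden:
                raise ConfigurationError("LSTM input must match top-RBM hidden size")

    @property
    def feature_dim(self) -> int:
        if self.variant == "au-4dbn-lstm":
            return self.lstm.units[-1]
        if self.variant == "au-4dbn":
            return self.top_rbm.n_hidden
        return self.base_dbn.top_dim


def build_sadn2d(
    spec: ArchitectureSpec,
    rng: np.random.Generator | None = None,
    dtype=np.float64,
) -> Sadn2D:
    """Randomly initialized three-channel appearance network."""
    rng = np.random.default_rng(rng)
    models = tuple(
        _dbn.init_dbn(spec.image_dim, list(spec.sadn_sizes), rng, dtype=dtype)
        for _ in range(3)
    )
    return Sadn2D(channel_models=models)


def build_dgdn3d(
    spec: ArchitectureSpec,
    variant: str = "au-4dbn-lstm",
    rng: np.random.Generator | None = None,
    dtype=np.float64,
) -> Dgdn3D:
    """Randomly initialized 3D-stream network of the requested variant."""
    rng = np.random.default_rng(rng)
    if variant == "4dbn":
        base = _dbn.init_dbn(spec.landmark_dim, list(spec.dgdn_sizes), rng, dtype=dtype)
        return Dgdn3D(variant=variant, base_dbn=base, n_aus=spec.n_aus)
    if variant == "4dbn-au":
        base = _dbn.init_dbn(
            spec.landmark_dim + spec.n_aus, list(spec.dgdn_sizes), rng, dtype=dtype
        )
        return Dgdn3D(variant=variant, base_dbn=base, n_aus=spec.n_aus)
    base = _dbn.init_dbn(spec.landmark_dim, list(spec.dgdn_sizes[:-1]), rng, dtype=dtype)
    top = _rbm.init_rbm(
        spec.top_rbm_visible, spec.top_rbm_hidden, GAUSSIAN, rng, dtype=dtype
    )
    top_head = rng.normal(0.0, 0.01, size=spec.top_rbm_hidden).astype(dtype)
    if variant == "au-4dbn":
        return Dgdn3D(
            variant=variant,
            base_dbn=base,
            top_rbm=top,
            top_head_weights=top_head,
            n_aus=spec.n_aus,
        )
    lstm = _lstm.init_lstm(spec.top_rbm_hidden, list(spec.lstm_units), rng)
    head = rng.normal(0.0, 0.01, size=spec.lstm_units[-1]).astype(dtype)
    return Dgdn3D(
        variant="au-4dbn-lstm",
        base_dbn=base,
        top_rbm=top,
        top_head_weights=top_head,
        lstm=lstm,
        lstm_head_weights=head,
        n_aus=spec.n_aus,
    )


def sadn2d_predict(model: Sadn2D, rgb_frame_vectors) -> tuple[float, np.ndarray]:
    """Score one frame given its three flattened channel vectors.

    Returns (probability, fused_feature): the probability is the mean of
    the three channel sigmoid outputs; the fused feature is the
    element-wise sum of the three top-layer activations.
    """
    if len(rgb_frame_vectors) != 3:
        raise DimensionMismatchError("expected three channel vectors (R, G, B)")
    probs, feats = [], []
    for vec, channel in zip(rgb_frame_vectors, model.channel_models):
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (model.input_dim,):
            raise DimensionMismatchError(
                f"channel vector length {vec.shape} != ({model.input_dim},)"
            )
        acts, p = _dbn.dbn_forward(channel, vec)
        probs.append(p)
        feats.append(acts[-1])
    return float(np.mean(probs)), np.sum(feats, axis=0)


def _au_features(model: Dgdn3D, frames: np.ndarray, aus: np.ndarray) -> np.ndarray:
    """Per-frame 150-d top-RBM hidden probabilities for the AU variants."""
    acts, _ = _dbn.dbn_forward_batch(model.base_dbn, frames)
    concat = np.concatenate([acts[-1], aus], axis=1)
    return _rbm.hidden_conditional(concat, model.top_rbm)


def dgdn3d_forward(
    model: Dgdn3D, frames: np.ndarray, aus: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Score a session (sequence of normalized frame vectors).

    DBN-only variants score each frame and average over the session; the
    LSTM variant runs the per-frame 150-d features through the stacked
    LSTM and scores the final hidden state. Returns
    (session probability, top feature vector).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if model.variant in ("4dbn", "4dbn-au"):
        if model.variant == "4dbn-au":
            want = model.base_dbn.n_input
            if frames.shape[1] == want - model.n_aus:
                if aus is None:
                    raise InvalidInputError("4dbn-au requires AU intensities")
                frames = np.concatenate([frames, np.atleast_2d(aus)], axis=1)
        acts, probs = _dbn.dbn_forward_batch(model.base_dbn, frames)
        return float(np.mean(probs)), acts[-1].mean(axis=0)
    if aus is None:
        raise InvalidInputError(f"{model.variant} requires AU intensities")
    aus = np.atleast_2d(np.asarray(aus, dtype=float))
    if aus.shape != (frames.shape[0], model.n_aus):
        raise DimensionMismatchError("AU matrix must be (frames, n_aus)")
    feats = _au_features(model, frames, aus)
    if model.variant == "au-4dbn":
        probs = _sigmoid(feats @ model.top_head_weights + model.top_head_bias)
        return float(np.mean(probs)), feats.mean(axis=0)
    outputs, _, _ = _lstm.lstm_forward_cached(feats, model.lstm)
    final = outputs[-1]
    prob = float(_sigmoid(final @ model.lstm_head_weights + model.lstm_head_bias))
    return prob, final


def _sizes_for_depth(base: tuple[int, ...], depth: int) -> list[int]:
    sizes = list(base[:depth])
    while len(sizes) < depth:
        sizes.append(max(2, sizes[-1] // 2))
    return sizes


def depth_sweep(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    depths: list[int],
    cd_cfg: CdConfig,
    ft_cfg: FineTuneConfig,
    rng: np.random.Generator,
    base_sizes: tuple[int, ...] = (3000, 2048, 1024, 128),
) -> pd.DataFrame:
    """Validation accuracy of DBNs of increasing depth (exploratory)."""
    if any(d < 1 or d > 5 for d in depths):
        raise ConfigurationError("depths must lie in 1..5")
    rows = []
    for depth in depths:
        sizes = _sizes_for_depth(base_sizes, depth)
        model = _dbn.pretrain_dbn(train_x, sizes, cd_cfg, rng, sparsity_layers=())
        model = _dbn.fine_tune(model, train_x, train_y, ft_cfg, rng)
        _, probs = _dbn.dbn_forward_batch(model, val_x)
        acc = float(np.mean((probs >= 0.5).astype(float) == np.asarray(val_y)))
        rows.append({"depth": depth, "accuracy": acc})
    return pd.DataFrame(rows)
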