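"""User-facing modelling interface.

``TwoStreamModel`` is built from a list of recording sessions and a layer
preset; ``fit()`` runs the full training pipeline — greedy contrastive-
divergence pretraining of both streams, per-stream supervised fine-tuning,
then joint fine-tuning under the weighted three-term loss — and returns a
``TwoStreamResults`` carrying the trained network, training history and
prediction/summary methods.

    >>> sessions, _ = generate_cohort(CohortSpec.desk(effect_size=2.0))
    >>> res = TwoStreamModel(sessions, spec="desk").fit(seed=0)
    >>> res.predict().head()
    >>> print(res.summary())
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dbn as _dbn
from . import fusion as _fusion
from . import rbm as _rbm
from .architectures import ArchitectureSpec, build_dgdn3d, build_sadn2d
from .dbn import FineTuneConfig
from .errors import ConfigurationError, InvalidInputError
from .fusion import FusionConfig, JointNetwork, SessionFeatures
from .preprocess import Session, session_to_features
from .rbm import CdConfig, GAUSSIAN

__all__ = ["TrainingConfig", "TwoStreamModel", "TwoStreamResults", "cv_fit_predict"]


def _expit(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


def _logit_clip(p, eps: float = 1e-6):
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _platt(z: np.ndarray, y: np.ndarray, iters: int = 200) -> tuple[float, float]:
    """Slope-only logistic recalibration p = sigmoid(a z), a >= 0.

    A slope-only (temperature) rescale never flips a stream's own
    decisions — it only sets how much log-odds weight the stream carries
    in the fused sum. The slope is clamped to [0, 20]: a stream that is
    uninformative on the validation subjects contributes nothing.
    """
    a = 1.0
    for _ in range(iters):
        p = _expit(a * z)
        g = np.sum((p - y) * z)
        h = np.sum(p * (1.0 - p) * z * z) + 1e-9
        step = g / h
        a -= step
        a = min(max(a, 0.0), 20.0)
        if abs(step) < 1e-10:
            break
    return float(a), 0.0


@dataclass(frozen=True)
class TrainingConfig:
    """Schedules of the three training phases.

    ``paper()`` mirrors the published schedule (100 CD epochs, 100/50
    fine-tune epochs); ``fast()`` is the workstation schedule used for
    cross-validation experiments at desk scale — identical machinery,
    shorter schedules and a cap on the number of frames fed to CD.
    """

    cd2d: CdConfig = field(default_factory=lambda: CdConfig())
    cd3d: CdConfig = field(default_factory=lambda: CdConfig(sparsity_weight=0.0))
    cd_top: CdConfig = field(default_factory=lambda: CdConfig(sparsity_weight=0.0))
    ft2d: FineTuneConfig = field(default_factory=FineTuneConfig)
    ft3d_base: FineTuneConfig = field(default_factory=FineTuneConfig)
    ft3d: FineTuneConfig = field(default_factory=lambda: FineTuneConfig(epochs=50))
    joint: FineTuneConfig = field(default_factory=lambda: FineTuneConfig(epochs=10))
    fusion: FusionConfig = field(default_factory=FusionConfig)
    max_cd_frames: int = 100_000
    max_bp_frames: int = 1_000_000
    sample_hidden: bool = False
    rescale: bool = True  # standardize inter-layer representations in pretraining
    aggregate2d: str = "mean-frame"  # or "mean-prob": average per-frame scores
    restarts3d: int = 1  # LSTM-stage restarts scored on the validation set
    restarts2d: int = 1  # channel fine-tune restarts scored on the validation set

    @classmethod
    def paper(cls) -> "TrainingConfig":
        return cls()

    @classmethod
    def fast(cls) -> "TrainingConfig":
        """Short schedule for repeated (cross-validated) fits."""
        return cls(
            cd2d=CdConfig(epochs=5, minibatch_size=100),
            cd3d=CdConfig(epochs=5, minibatch_size=100, sparsity_weight=0.0),
            cd_top=CdConfig(epochs=5, minibatch_size=100, sparsity_weight=0.0),
            ft2d=FineTuneConfig(
                epochs=60, learning_rate=0.1, minibatch_size=60, weight_decay=1e-3
            ),
            # at this scale the frame-level discriminative pass over the 3D
            # base memorizes training subjects without helping held-out
            # sessions; the joint phase still adapts the base end-to-end
            ft3d_base=FineTuneConfig(epochs=0, learning_rate=0.3, minibatch_size=100),
            ft3d=FineTuneConfig(epochs=200, learning_rate=0.3, minibatch_size=40),
            joint=FineTuneConfig(epochs=4, learning_rate=0.05, minibatch_size=20),
            max_cd_frames=600,
            max_bp_frames=720,
            restarts3d=2,
            restarts2d=2,
        )


@dataclass(frozen=True)
class InputStandardizer:
    """Per-dimension training-set standardization of all three streams.

    Gaussian-visible RBMs assume roughly zero-mean unit-variance inputs;
    raw [0,1] pixel vectors and per-frame-normalized landmark vectors both
    carry a large common component (the mean face), which saturates the
    first hidden layer. Centering/scaling against the training cohort —
    i.e. modelling deviation from the mean face — removes it. Statistics
    are estimated on the training sessions only and reapplied at
    prediction time.
    """

    ch_mu: np.ndarray
    ch_sd: np.ndarray
    f3_mu: np.ndarray
    f3_sd: np.ndarray
    au_mu: np.ndarray
    au_sd: np.ndarray

    @classmethod
    def fit(cls, features: list[SessionFeatures]) -> "InputStandardizer":
        def stats(x):
            mu, sd = x.mean(axis=0), x.std(axis=0)
            sd = np.where(sd < 1e-8, 1.0, sd)
            return mu, sd

        ch = np.concatenate([f.channels for f in features], axis=1)  # (3, N, D)
        ch_mu = ch.mean(axis=1)
        ch_sd = np.where(ch.std(axis=1) < 1e-8, 1.0, ch.std(axis=1))
        f3_mu, f3_sd = stats(np.concatenate([f.frames3d for f in features]))
        au_mu, au_sd = stats(np.concatenate([f.aus for f in features]))
        return cls(ch_mu, ch_sd, f3_mu, f3_sd, au_mu, au_sd)

    def apply(self, f: SessionFeatures) -> SessionFeatures:
        return SessionFeatures(
            channels=(f.channels - self.ch_mu[:, None, :]) / self.ch_sd[:, None, :],
            frames3d=(f.frames3d - self.f3_mu) / self.f3_sd,
            aus=(f.aus - self.au_mu) / self.au_sd,
            label=f.label,
        )


class TwoStreamModel:
    """Two-stream depression-risk recognizer over multimodal sessions.

    Parameters
    ----------
    sessions : list of Session
        Aligned image + landmark/AU recordings with binary labels.
    spec : ArchitectureSpec or preset name
        Layer sizes; must match the stored image size.
    config : TrainingConfig, optional
    """

    def __init__(
        self,
        sessions: list[Session],
        spec: ArchitectureSpec | str = "desk",
        config: TrainingConfig | None = None,
    ):
        if not sessions:
            raise InvalidInputError("no sessions given")
        self.spec = ArchitectureSpec.preset(spec) if isinstance(spec, str) else spec
        self.config = config if config is not None else TrainingConfig.fast()
        img = sessions[0].frames_rgb.shape[1]
        if img != self.spec.image_size:
            raise ConfigurationError(
                f"sessions hold {img}x{img} images but the preset expects "
                f"{self.spec.image_size}x{self.spec.image_size}"
            )
        self.sessions = sessions
        self.features: list[SessionFeatures] = []
        for s in sessions:
            ch, f3, au = session_to_features(s)
            self.features.append(
                SessionFeatures(channels=ch, frames3d=f3, aus=au, label=s.label)
            )
        self.labels = np.array([s.label for s in sessions])
        self.meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in sessions],
                "task": [s.task for s in sessions],
                "valence": [s.valence for s in sessions],
                "gender": [s.gender for s in sessions],
                "label": self.labels,
            }
        )

    # -- training ----------------------------------------------------------

    def fit(
        self, seed: int = 0, val_sessions: list[Session] | None = None
    ) -> "TwoStreamResults":
        """Train the full pipeline.

        When ``val_sessions`` is given, stream fine-tuning restarts
        (``restarts2d`` / ``restarts3d``) are scored on the held-out
        validation subjects and the best restart is kept — the validation
        fold's role in the study protocol.
        """
        cfg = self.config
        spec = self.spec
        t0 = time.time()
        history: dict[str, list[float]] = {}

        standardizer = InputStandardizer.fit(self.features)
        features = [standardizer.apply(f) for f in self.features]
        val_feats, val_labels = None, None
        if val_sessions:
            val_feats = []
            for s in val_sessions:
                ch, f3, au = session_to_features(s)
                val_feats.append(
                    standardizer.apply(
                        SessionFeatures(channels=ch, frames3d=f3, aus=au, label=s.label)
                    )
                )
            val_labels = np.array([s.label for s in val_sessions])

        frame_labels = np.concatenate(
            [np.full(f.frames3d.shape[0], f.label) for f in features]
        )
        channels_all = [
            np.concatenate([f.channels[c] for f in features]) for c in range(3)
        ]
        frames3d_all = np.concatenate([f.frames3d for f in features])
        aus_all = np.concatenate([f.aus for f in features])

        # --- 2D stream: greedy CD pretraining on frames, BP fine-tuning on
        # session-mean appearance vectors (denoised static appearance)
        pretrained = []
        means_per_channel = []
        for c in range(3):
            rng = np.random.default_rng([seed, 11, c])
            x = channels_all[c]
            sub = self._cd_subset(x, rng)
            pretrained.append(
                _dbn.pretrain_dbn(
                    sub, list(spec.sadn_sizes), cfg.cd2d, rng,
                    sparsity_layers=(0,), sample_hidden=cfg.sample_hidden,
                    rescale=cfg.rescale,
                )
            )
            means_per_channel.append(
                np.stack([f.channels[c].mean(axis=0) for f in features])
            )
        n2 = cfg.restarts2d if val_feats is not None else 1
        best2, best2_acc = None, -1.0
        if cfg.aggregate2d == "mean-frame":
            ft2d_data = [(means_per_channel[c], self.labels) for c in range(3)]
        else:
            rng2 = np.random.default_rng([seed, 13])
            sel = self._bp_subset(channels_all[0].shape[0], rng2)
            ft2d_data = [
                (channels_all[c][sel], frame_labels[sel]) for c in range(3)
            ]
        for r in range(n2):
            channel_models = [
                _dbn.fine_tune(
                    pretrained[c], ft2d_data[c][0], ft2d_data[c][1], cfg.ft2d,
                    np.random.default_rng([seed, 11, c, r]),
                )
                for c in range(3)
            ]
            if n2 == 1:
                best2 = channel_models
                break
            acc = self._val_acc_2d(channel_models, val_feats, val_labels, cfg.aggregate2d)
            if acc > best2_acc:
                best2, best2_acc = channel_models, acc
        from .architectures import Sadn2D

        sadn = Sadn2D(channel_models=tuple(best2))

        # --- 3D stream: base DBN CD, top RBM CD, LSTM-head supervised pass
        rng3 = np.random.default_rng([seed, 23])
        base = _dbn.pretrain_dbn(
            self._cd_subset(frames3d_all, rng3),
            list(spec.dgdn_sizes[:-1]),
            cfg.cd3d,
            rng3,
            sparsity_layers=(),
            sample_hidden=cfg.sample_hidden,
            rescale=cfg.rescale,
        )
        bp_sel = self._bp_subset(frames3d_all.shape[0], rng3)
        base = _dbn.fine_tune(
            base, frames3d_all[bp_sel], frame_labels[bp_sel], cfg.ft3d_base, rng3
        )
        acts, _ = _dbn.dbn_forward_batch(base, frames3d_all)
        concat_all = np.concatenate([acts[-1], aus_all], axis=1)
        top = _rbm.init_rbm(spec.top_rbm_visible, spec.top_rbm_hidden, GAUSSIAN, rng3)
        if cfg.rescale:
            mu, sd = concat_all.mean(axis=0), concat_all.std(axis=0)
            sd = np.where(sd < 1e-8, 1.0, sd)
            top = _rbm.train_rbm(
                self._cd_subset((concat_all - mu) / sd, rng3), top, cfg.cd_top, rng3
            )
            top = _rbm.absorb_input_affine(top, mu, sd)
        else:
            top = _rbm.train_rbm(self._cd_subset(concat_all, rng3), top, cfg.cd_top, rng3)

        from . import lstm as _lstm
        from .architectures import Dgdn3D

        concat_list, start = [], 0
        for f in features:
            T = f.frames3d.shape[0]
            concat_list.append(concat_all[start : start + T])
            start += T
        n3 = cfg.restarts3d if val_feats is not None else 1
        best3, best3_acc = None, -1.0
        for r in range(n3):
            rng_r = np.random.default_rng([seed, 29, r])
            lstm = _lstm.init_lstm(
                spec.top_rbm_hidden, list(spec.lstm_units), rng_r, weight_scale=0.3
            )
            cand = Dgdn3D(
                variant="au-4dbn-lstm",
                base_dbn=base,
                top_rbm=top,
                top_head_weights=rng_r.normal(0.0, 0.01, size=spec.top_rbm_hidden),
                lstm=lstm,
                lstm_head_weights=rng_r.normal(0.0, 0.01, size=spec.lstm_units[-1]),
                n_aus=spec.n_aus,
            )
            cand = _fusion.fit_stream3d(cand, concat_list, self.labels, cfg.ft3d, rng_r)
            if n3 == 1:
                best3 = cand
                break
            acc = self._val_acc_3d(cand, val_feats, val_labels)
            if acc > best3_acc:
                best3, best3_acc = cand, acc
        dgdn = best3

        # --- joint fine-tuning under the weighted three-term loss
        rngj = np.random.default_rng([seed, 37])
        net = _fusion.init_joint(sadn, dgdn, rngj)
        net, joint_hist = _fusion.fit_joint(
            net, features, cfg.fusion, cfg.joint, rngj, aggregate2d=cfg.aggregate2d
        )
        history["joint_loss"] = joint_hist
        res = TwoStreamResults(
            model=self,
            network=net,
            history=history,
            standardizer=standardizer,
            fit_seconds=time.time() - t0,
        )
        # label-free fusion scales: SD of each vote's training log-odds.
        # Overconfident (typically overfit) votes get proportionally less
        # weight in the fused sum; votes are never amplified (floor 1).
        train_pred = res.predict()
        res.logit_scales = {
            name: max(float(_logit_clip(train_pred[f"p_{name}"]).std()), 1.0)
            for name in ("2d", "3d", "head")
        }
        return res

    def _cd_subset(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if x.shape[0] <= self.config.max_cd_frames:
            return x
        sel = rng.choice(x.shape[0], size=self.config.max_cd_frames, replace=False)
        return x[sel]

    def _bp_subset(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n <= self.config.max_bp_frames:
            return np.arange(n)
        return rng.choice(n, size=self.config.max_bp_frames, replace=False)

    @staticmethod
    def _val_acc_2d(channel_models, val_feats, val_labels, aggregate2d="mean-frame") -> float:
        probs = []
        for f in val_feats:
            if aggregate2d == "mean-frame":
                ps = [
                    _dbn.dbn_forward_batch(m, f.channels[c].mean(axis=0)[None, :])[1][0]
                    for c, m in enumerate(channel_models)
                ]
            else:
                ps = [
                    _dbn.dbn_forward_batch(m, f.channels[c])[1].mean()
                    for c, m in enumerate(channel_models)
                ]
            probs.append(np.mean(ps))
        return float(np.mean((np.asarray(probs) >= 0.5) == val_labels))

    @staticmethod
    def _val_acc_3d(dgdn, val_feats, val_labels) -> float:
        from .architectures import dgdn3d_forward

        probs = [dgdn3d_forward(dgdn, f.frames3d, f.aus)[0] for f in val_feats]
        return float(np.mean((np.asarray(probs) >= 0.5) == val_labels))


@dataclass
class TwoStreamResults:
    """Fitted two-stream network plus diagnostics."""

    model: TwoStreamModel
    network: JointNetwork
    history: dict
    standardizer: InputStandardizer | None = None
    fit_seconds: float = float("nan")
    calibration: dict | None = None  # per-stream Platt scaling (a, b)
    logit_scales: dict | None = None  # training-set log-odds SD per vote

    def calibrate(self, sessions: list[Session], by_valence: bool = False) -> "TwoStreamResults":
        """Rescale each stream's log-odds on held-out (validation) data.

        Logit-sum fusion adds stream log-odds, so an overconfident or
        uninformative stream distorts the sum; a slope-only rescale fit on
        the validation subjects sets each stream's weight without flipping
        its decisions. With ``by_valence`` a separate slope is fit per
        stimulus valence (the protocol records which valence was shown,
        and stream reliability is strongly valence-dependent), falling
        back to the pooled slope for sparse cells. Returns self.
        """
        self.calibration = None
        pred = self.predict(sessions)
        y = pred["label"].to_numpy().astype(float)
        calib: dict = {}
        for name in ("2d", "3d"):
            z = _logit_clip(pred[f"p_{name}"].to_numpy())
            pooled = _platt(z, y)
            calib[name] = {"*": pooled}
            if by_valence:
                for val in pred["valence"].unique():
                    m = (pred["valence"] == val).to_numpy()
                    if m.sum() >= 12 and len(np.unique(y[m])) == 2:
                        calib[name][val] = _platt(z[m], y[m])
        # guard: if the calibrated fusion underperforms the better single
        # stream on the validation subjects, drop the weaker stream from
        # the sum (its slope goes to zero) — validation-based selection
        # within the fusion family
        z2 = _logit_clip(pred["p_2d"].to_numpy())
        z3 = _logit_clip(pred["p_3d"].to_numpy())
        acc = {
            "2d": float(np.mean((z2 >= 0) == y)),
            "3d": float(np.mean((z3 >= 0) == y)),
        }
        fused = calib["2d"]["*"][0] * z2 + calib["3d"]["*"][0] * z3
        acc_fused = float(np.mean((fused >= 0) == y))
        if acc_fused < max(acc.values()):
            weaker = "2d" if acc["2d"] <= acc["3d"] else "3d"
            calib[weaker] = {"*": (0.0, 0.0)}
        self.calibration = calib
        return self

    def _calibrated_logit(self, name: str, p: float, valence: str) -> float:
        a, b = self.calibration[name].get(valence, self.calibration[name]["*"])
        return a * float(_logit_clip(p)) + b

    def predict(self, sessions: list[Session] | None = None, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-session probabilities and fused decisions.

        Columns: p_2d, p_3d (stream outputs), p_joint (logit-sum fusion,
        the reported rule), p_head (fully connected fusion head) and the
        predicted class (p_joint >= 0.5).
        """
        if sessions is None:
            feats = self.model.features
            meta = self.model.meta
        else:
            feats = []
            for s in sessions:
                ch, f3, au = session_to_features(s)
                feats.append(SessionFeatures(channels=ch, frames3d=f3, aus=au, label=s.label))
            meta = pd.DataFrame(
                {
                    "subject_id": [s.subject_id for s in sessions],
                    "task": [s.task for s in sessions],
                    "valence": [s.valence for s in sessions],
                    "gender": [s.gender for s in sessions],
                    "label": [s.label for s in sessions],
                }
            )
        if self.standardizer is not None:
            feats = [self.standardizer.apply(f) for f in feats]
        valences = meta["valence"].tolist()
        rows = []
        for f, valence in zip(feats, valences):
            cache = _fusion.joint_forward(
                self.network, f, aggregate2d=self.model.config.aggregate2d
            )
            p2d, p3d = cache["p2d"], cache["p3d"]
            if self.calibration is not None:
                # slope-only calibration never flips a stream's own
                # decision, so p_2d/p_3d stay raw; only the fusion uses
                # the reweighted log-odds
                l2 = self._calibrated_logit("2d", p2d, valence)
                l3 = self._calibrated_logit("3d", p3d, valence)
                p_fused = float(_expit(l2 + l3))
            elif self.logit_scales is not None:
                # shipped rule: scale-normalized log-odds sum of the two
                # streams plus the trained fusion head's vote
                s = self.logit_scales
                p_fused = float(
                    _expit(
                        _logit_clip(p2d) / s["2d"]
                        + _logit_clip(p3d) / s["3d"]
                        + _logit_clip(cache["p23"]) / s["head"]
                    )
                )
            else:
                p_fused = cache["p_fused"]
            rows.append(
                {
                    "p_2d": p2d,
                    "p_3d": p3d,
                    "p_joint": p_fused,
                    "p_head": cache["p23"],
                }
            )
        out = pd.concat([meta.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
        out["predicted"] = (out["p_joint"] >= 0.5).astype(int)
        return out

    def summary(self) -> str:
        spec = self.model.spec
        pred = self.predict()
        acc = {
            name: float(np.mean((pred[f"p_{name}"] >= 0.5).astype(int) == pred["label"]))
            for name in ("2d", "3d", "joint")
        }
        lines = [
            "Two-stream depression-risk model",
            "=" * 48,
            f"sessions: {len(self.model.sessions)}   subjects: {self.model.meta['subject_id'].nunique()}",
            f"2D-SADN channels: {spec.image_dim}-" + "-".join(map(str, spec.sadn_sizes)) + " x3",
            f"3D stream: {spec.landmark_dim}-" + "-".join(map(str, spec.dgdn_sizes[:-1]))
            + f" (+{spec.n_aus} AU) -> RBM {spec.top_rbm_visible}->{spec.top_rbm_hidden}"
            + f" -> LSTM {spec.lstm_units[0]}->{spec.lstm_units[1]}",
            f"fusion: scale-normalized logit sum + head vote over {spec.sadn_sizes[-1]}+{spec.lstm_units[-1]} features",
            f"joint loss (final epoch): {self.history['joint_loss'][-1]:.4f}"
            if self.history.get("joint_loss")
            else "joint loss: n/a",
            f"training accuracy  2D {acc['2d']:.3f}   3D {acc['3d']:.3f}   joint {acc['joint']:.3f}",
            f"fit time: {self.fit_seconds:.1f} s",
        ]
        return "\n".join(lines)


def cv_fit_predict(
    spec: ArchitectureSpec | str = "desk",
    config: TrainingConfig | None = None,
):
    """Adapter for ``evaluate.run_cv``: trains a TwoStreamModel per round.

    Returns a ``fit_predict(train, val, seed)`` closure whose predictor
    reports '2d', '3d' and 'joint' (logit-sum) probabilities.
    """

    def fit_predict(train: list[Session], val: list[Session], seed: int):
        # validation subjects drive restart selection inside fit(); the
        # shipped fusion rule itself is label-free (training logit scales)
        res = TwoStreamModel(train, spec=spec, config=config).fit(
            seed=seed, val_sessions=val or None
        )

        def predictor(test: list[Session]) -> dict[str, np.ndarray]:
            pred = res.predict(test)
            return {
                "2d": pred["p_2d"].to_numpy(),
                "3d": pred["p_3d"].to_numpy(),
                "joint": pred["p_joint"].to_numpy(),
            }

        return predictor

    return fit_predict
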