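"""Model persistence: one .npz array container plus a JSON manifest.

The manifest records layer families, dimensions, sigma and the variant so
a saved network can be rebuilt without guessing; arrays live in the .npz
keyed by component ("ch0.w0", "base.b2", "lstm1.w_xf", "joint.w", ...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .architectures import Dgdn3D, Sadn2D
from .dbn import DbnModel
from .fusion import JointNetwork
from .lstm import LstmLayerParams, LstmParams
from .rbm import RbmParams

__all__ = ["save_network", "load_network", "save_dbn", "load_dbn"]


def _dbn_arrays(model: DbnModel, prefix: str, arrays: dict, manifest: dict) -> None:
    manifest[prefix] = {
        "layer_sizes": model.layer_sizes,
        "families": [l.visible_family for l in model.layers],
        "sigmas": [l.sigma for l in model.layers],
    }
    for i, layer in enumerate(model.layers):
        arrays[f"{prefix}.w{i}"] = layer.weights
        arrays[f"{prefix}.vb{i}"] = layer.visible_bias
        arrays[f"{prefix}.hb{i}"] = layer.hidden_bias
    arrays[f"{prefix}.head_w"] = model.head_weights
    arrays[f"{prefix}.head_b"] = np.asarray(model.head_bias)


def _dbn_from_arrays(prefix: str, arrays, manifest: dict) -> DbnModel:
    info = manifest[prefix]
    layers = tuple(
        RbmParams(
            weights=arrays[f"{prefix}.w{i}"],
            visible_bias=arrays[f"{prefix}.vb{i}"],
            hidden_bias=arrays[f"{prefix}.hb{i}"],
            sigma=info["sigmas"][i],
            visible_family=info["families"][i],
        )
        for i in range(len(info["layer_sizes"]) - 1)
    )
    return DbnModel(
        layers=layers,
        head_weights=arrays[f"{prefix}.head_w"],
        head_bias=float(arrays[f"{prefix}.head_b"]),
    )


def save_dbn(model: DbnModel, path: str | Path) -> Path:
    path = Path(path)
    arrays: dict = {}
    manifest: dict = {"kind": "dbn"}
    _dbn_arrays(model, "dbn", arrays, manifest)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path


def load_dbn(path: str | Path) -> DbnModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arrays:
        return _dbn_from_arrays("dbn", arrays, manifest)


def save_network(net: JointNetwork, path: str | Path) -> Path:
    """Write <path>.npz + <path>.json for a full joint network."""
    path = Path(path)
    arrays: dict = {}
    manifest: dict = {"kind": "joint", "variant": net.dgdn.variant, "n_aus": net.dgdn.n_aus}
    for c, m in enumerate(net.sadn.channel_models):
        _dbn_arrays(m, f"ch{c}", arrays, manifest)
    _dbn_arrays(net.dgdn.base_dbn, "base", arrays, manifest)
    top = net.dgdn.top_rbm
    manifest["top"] = {"sigma": top.sigma, "family": top.visible_family}
    arrays["top.w"] = top.weights
    arrays["top.vb"] = top.visible_bias
    arrays["top.hb"] = top.hidden_bias
    arrays["top.head_w"] = net.dgdn.top_head_weights
    arrays["top.head_b"] = np.asarray(net.dgdn.top_head_bias)
    manifest["lstm_units"] = net.dgdn.lstm.units
    for li, lp in enumerate(net.dgdn.lstm.layers):
        for name in lp.__dataclass_fields__:
            arrays[f"lstm{li}.{name}"] = getattr(lp, name)
    arrays["head3d.w"] = net.dgdn.lstm_head_weights
    arrays["head3d.b"] = np.asarray(net.dgdn.lstm_head_bias)
    arrays["joint.w"] = net.joint_weights
    arrays["joint.b"] = np.asarray(net.joint_bias)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path


def load_network(path: str | Path) -> JointNetwork:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arrays:
        sadn = Sadn2D(
            channel_models=tuple(_dbn_from_arrays(f"ch{c}", arrays, manifest) for c in range(3))
        )
        lstm_layers = []
        for li in range(len(manifest["lstm_units"])):
            kw = {
                name: arrays[f"lstm{li}.{name}"]
                for name in LstmLayerParams.__dataclass_fields__
            }
            lstm_layers.append(LstmLayerParams(**kw))
        dgdn = Dgdn3D(
            variant=manifest["variant"],
            base_dbn=_dbn_from_arrays("base", arrays, manifest),
            top_rbm=RbmParams(
                weights=arrays["top.w"],
                visible_bias=arrays["top.vb"],
                hidden_bias=arrays["top.hb"],
                sigma=manifest["top"]["sigma"],
                visible_family=manifest["top"]["family"],
            ),
            top_head_weights=arrays["top.head_w"],
            top_head_bias=float(arrays["top.head_b"]),
            lstm=LstmParams(layers=tuple(lstm_layers)),
            lstm_head_weights=arrays["head3d.w"],
            lstm_head_bias=float(arrays["head3d.b"]),
            n_aus=manifest["n_aus"],
        )
        return JointNetwork(
            sadn=sadn,
            dgdn=dgdn,
            joint_weights=arrays["joint.w"],
            joint_bias=float(arrays["joint.b"]),
        )
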