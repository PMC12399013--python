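"""Architecture definition and construction for the MSFE-GallNet-X classifier.

The network is a six-stage convolutional stack over 128x128 single-channel
ultrasound images.  Each stage is either a plain same-padded convolution or a
multi-scale feature-extraction (MSFE) block — three parallel 1x1 / 3x3 / 5x5
convolution branches, batch-normalized, ReLU-activated, channel-concatenated
and batch-normalized again — and every stage ends in a 2x2 max-pool, so six
stages reduce 128 -> 2.  A 256/128 dense head with dropout and an L2 weight
penalty feeds a 9-way softmax.

Two configurations are pinned:

* :func:`default_full_config` — two MSFE stages (positions 2 and 4);
  1,907,705 trainable parameters (1.91 M).
* :func:`default_ablation_config` — the multi-scale blocks removed, i.e. six
  plain 3x3 stages tuned as the narrower "without MSFE" variant;
  865,209 trainable parameters (0.87 M).

The per-stage filter counts are free configuration; the pinned defaults are
chosen so the two trainable-parameter budgets above are met exactly.

This module also carries reference implementations of the primitive
operations (valid-region cross-correlation, ReLU, softmax) that the layer
implementations in :mod:`gallnet.nn` are tested against.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import softmax

__all__ = [
    "ConfigError",
    "ConvStageSpec",
    "MSFEBlockSpec",
    "DenseHeadSpec",
    "ArchitectureConfig",
    "Model",
    "conv2d_reference",
    "relu",
    "softmax",
    "build_msfe_block",
    "build_model",
    "count_trainable_parameters",
    "default_full_config",
    "default_ablation_config",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigError(ValueError):
    """Raised when an architecture configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Reference primitive operations
# ---------------------------------------------------------------------------

def relu(x):
    """Rectified linear unit: x if x > 0, else 0 (element-wise)."""
    return np.maximum(x, 0)


def conv2d_reference(inputs: np.ndarray, kernels: np.ndarray,
                     bias: np.ndarray | None = None) -> np.ndarray:
    """Valid (un-padded) 2-D cross-correlation, the test oracle for the
    network's convolution layers.

    Parameters
    ----------
    inputs : (m1, m2, mc) array
        Feature map indexed (row i, column j, channel z).
    kernels : (k1, k2, mc, F) array
        Filter weights indexed (x, y, z, output filter).
    bias : (F,) array, optional
        Per-filter bias, default zero.

    Returns
    -------
    (m1 - k1 + 1, m2 - k2 + 1, F) array where entry (i, j, f) is
    ``sum_{x,y,z} K[x, y, z, f] * I[i + x - 1, j + y - 1, z]`` in 1-based
    index arithmetic — i.e. the inner product of the filter with the input
    patch whose top-left corner is (i, j), no kernel flip.
    """
    inputs = np.asarray(inputs, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if inputs.ndim != 3 or kernels.ndim != 4:
        raise ValueError("inputs must be (m1, m2, mc); kernels (k1, k2, mc, F)")
    m1, m2, mc = inputs.shape
    k1, k2, kc, nf = kernels.shape
    if kc != mc:
        raise ValueError(f"channel mismatch: input has {mc}, kernel expects {kc}")
    if k1 > m1 or k2 > m2:
        raise ValueError("kernel spatial extents exceed input extents")
    if bias is None:
        bias = np.zeros(nf)
    out = np.empty((m1 - k1 + 1, m2 - k2 + 1, nf))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            patch = inputs[i:i + k1, j:j + k2, :]
            out[i, j, :] = np.tensordot(patch, kernels, axes=3) + bias
    return out


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvStageSpec:
    """One plain convolutional stage: same-padded conv -> BN -> ReLU ->
    2x2 max-pool."""

    filters: int
    kernel_size: int = 3

    def __post_init__(self):
        if self.filters < 1:
            raise ConfigError("filter count must be positive")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ConfigError("kernel size must be an odd positive integer")

    @property
    def out_channels(self) -> int:
        return self.filters


@dataclass(frozen=True)
class MSFEBlockSpec:
    """A multi-scale feature-extraction stage: parallel 1x1/3x3/5x5
    branches (conv -> BN -> ReLU each), channel concatenation, post-merge
    BN, 2x2 max-pool."""

    f1: int
    f3: int
    f5: int

    def __post_init__(self):
        if min(self.f1, self.f3, self.f5) < 1:
            raise ConfigError("branch filter counts must be positive")

    @property
    def out_channels(self) -> int:
        return self.f1 + self.f3 + self.f5


@dataclass(frozen=True)
class DenseHeadSpec:
    """Classifier head: two hidden dense layers (ReLU + dropout each) and a
    softmax output layer, with an L2 penalty on all dense weights."""

    hidden: tuple[int, int] = (256, 128)
    dropout: float = 0.1
    l2: float = 0.01

    def __post_init__(self):
        if len(self.hidden) != 2 or min(self.hidden) < 1:
            raise ConfigError("head must have exactly two positive hidden widths")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout rate must be in [0, 1)")
        if self.l2 < 0:
            raise ConfigError("L2 coefficient must be nonnegative")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Full declarative description of the network; determines the
    trainable-parameter count exactly."""

    stages: tuple = ()
    head: DenseHeadSpec = field(default_factory=DenseHeadSpec)
    input_size: int = 128
    in_channels: int = 1
    n_classes: int = 9

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        if len(self.stages) != 6:
            raise ConfigError(f"expected exactly 6 stages, got {len(self.stages)}")
        n_msfe = sum(isinstance(s, MSFEBlockSpec) for s in self.stages)
        if n_msfe not in (0, 2):
            raise ConfigError(
                f"expected exactly two MSFE stages (or none for the ablation), got {n_msfe}")
        if self.input_size % 64 != 0 or self.input_size <= 0:
            raise ConfigError("input size must be a positive multiple of 64")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")

    @property
    def final_spatial(self) -> int:
        return self.input_size // 2 ** len(self.stages)

    @property
    def final_channels(self) -> int:
        return self.stages[-1].out_channels


def default_full_config() -> ArchitectureConfig:
    """The pinned MSFE-GallNet-X configuration (1.91 M parameters)."""
    return ArchitectureConfig(stages=(
        ConvStageSpec(16),
        MSFEBlockSpec(16, 16, 16),
        ConvStageSpec(96),
        MSFEBlockSpec(32, 32, 32),
        ConvStageSpec(256),
        ConvStageSpec(448),
    ))


def default_ablation_config() -> ArchitectureConfig:
    """The pinned without-MSFE variant (0.87 M parameters)."""
    return ArchitectureConfig(stages=(
        ConvStageSpec(16),
        ConvStageSpec(32),
        ConvStageSpec(48),
        ConvStageSpec(96),
        ConvStageSpec(160),
        ConvStageSpec(256),
    ))


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class MSFEBlock(nn.Layer):
    """Composite layer: parallel 1x1/3x3/5x5 conv->BN->ReLU branches,
    channel concatenation, post-merge batch normalization.

    The 2x2 max-pool that closes an MSFE *stage* is a separate layer so
    that this block's output is the full-resolution merged feature map
    (the natural Grad-CAM probe point).
    """

    def __init__(self, c_in: int, spec: MSFEBlockSpec, name: str,
                 rng: np.random.Generator, dtype=np.float32):
        self.name = name
        self.spec = spec
        self.c_in = c_in
        self.branches = []
        for k, f in zip((1, 3, 5), (spec.f1, spec.f3, spec.f5)):
            self.branches.append([
                nn.Conv2D(c_in, f, k, f"{name}.b{k}.conv", rng, dtype=dtype),
                nn.BatchNorm(f, f"{name}.b{k}.bn", dtype=dtype),
                nn.ReLU(f"{name}.b{k}.relu"),
            ])
        self.merge_bn = nn.BatchNorm(spec.out_channels, f"{name}.merge_bn",
                                     dtype=dtype)
        self._splits = np.cumsum([spec.f1, spec.f3, spec.f5])[:-1]

    def forward(self, x, training=False, cache=None):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, training=training, cache=cache)
            outs.append(h)
        merged = np.concatenate(outs, axis=-1)
        return self.merge_bn.forward(merged, training=training, cache=cache)

    def backward(self, dout):
        dmerged = self.merge_bn.backward(dout)
        dparts = np.split(dmerged, self._splits, axis=-1)
        dx = None
        for branch, dpart in zip(self.branches, dparts):
            d = np.ascontiguousarray(dpart)
            for layer in reversed(branch):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx

    def _sublayers(self):
        for branch in self.branches:
            yield from branch
        yield self.merge_bn

    def params(self):
        out = {}
        for sub in self._sublayers():
            for key, val in sub.params().items():
                out[f"{sub.name}/{key}"] = val
        return out

    def grads(self):
        out = {}
        for sub in self._sublayers():
            for key, val in sub.grads().items():
                out[f"{sub.name}/{key}"] = val
        return out

    def state(self):
        out = {}
        for sub in self._sublayers():
            for key, val in sub.state().items():
                out[f"{sub.name}/{key}"] = val
        return out


def build_msfe_block(spec: MSFEBlockSpec, in_channels: int,
                     rng: np.random.Generator | None = None,
                     name: str = "msfe", dtype=np.float32) -> list[nn.Layer]:
    """Build one MSFE stage as a layer subgraph (block + closing pool).

    Output channel count is f1 + f3 + f5 and spatial extents are halved by
    the pool; the branches preserve spatial extent (same padding, no
    pooling inside the block).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    return [MSFEBlock(in_channels, spec, name, rng, dtype=dtype),
            nn.MaxPool2x2(f"{name}.pool")]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class Model:
    """A built network: an ordered list of named layers ending in a 9-way
    logit layer.  ``forward`` returns logits; ``predict_proba`` applies the
    softmax.  Any named layer's activations and the gradient of a class
    logit with respect to them are available through
    :meth:`activation_and_gradient` (used by Grad-CAM)."""

    def __init__(self, config: ArchitectureConfig, layers: list[nn.Layer],
                 dtype=np.float32):
        self.config = config
        self.layers = layers
        self.dtype = dtype
        self._by_name = {layer.name: layer for layer in layers}

    # -- naming ------------------------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def layer(self, name: str) -> nn.Layer:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no layer named {name!r}; have {self.layer_names}")

    @property
    def conv_stage_names(self) -> list[str]:
        """Names of the per-stage Grad-CAM probe points (pre-pool feature
        maps), in depth order."""
        names = []
        for layer in self.layers:
            if isinstance(layer, MSFEBlock):
                names.append(layer.name)
            elif isinstance(layer, nn.ReLU) and layer.name.endswith(".relu") \
                    and layer.name.startswith("stage"):
                names.append(layer.name)
        return names

    # -- forward / backward ------------------------------------------------

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[..., None] if x.shape[-1] != self.config.in_channels else x[None]
        if x.ndim != 4:
            raise ValueError(f"expected image batch, got shape {x.shape}")
        return x.astype(self.dtype, copy=False)

    def forward(self, x: np.ndarray, training: bool = False,
                cache: bool | None = None) -> np.ndarray:
        """Run the network; returns pre-softmax logits (N, n_classes)."""
        h = self._prepare(x)
        for layer in self.layers:
            h = layer.forward(h, training=training, cache=cache)
        return h

    def forward_collect(self, x: np.ndarray, names: set[str],
                        training: bool = False,
                        cache: bool | None = None):
        """Forward pass that also returns the outputs of the named layers."""
        h = self._prepare(x)
        collected = {}
        for layer in self.layers:
            h = layer.forward(h, training=training, cache=cache)
            if layer.name in names:
                collected[layer.name] = h
        return h, collected

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate from the logits; fills all parameter gradients and
        returns the gradient with respect to the input batch."""
        d = dlogits.astype(self.dtype, copy=False)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def backward_to(self, dlogits: np.ndarray, layer_name: str) -> np.ndarray:
        """Backpropagate from the logits and stop at the *output* of the
        named layer, returning the gradient arriving there."""
        if layer_name not in self._by_name:
            raise KeyError(f"no layer named {layer_name!r}")
        d = dlogits.astype(self.dtype, copy=False)
        for layer in reversed(self.layers):
            if layer.name == layer_name:
                return d
            d = layer.backward(d)
        raise AssertionError("unreachable")

    def activation_and_gradient(self, x: np.ndarray, class_index: int,
                                layer_name: str):
        """Inference-mode activations A of the named layer and the gradient
        dlogit_c/dA of the class logit with respect to them."""
        logits, acts = self.forward_collect(x, {layer_name}, training=False,
                                            cache=True)
        if acts[layer_name].ndim != 4:
            raise ValueError(f"layer {layer_name!r} has no spatial activations")
        n, c = logits.shape
        if not 0 <= class_index < c:
            raise IndexError(f"class index {class_index} out of range 0..{c - 1}")
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        grad = self.backward_to(dlogits, layer_name)
        return acts[layer_name], grad, logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._prepare(x)
        chunks = [softmax(self.forward(x[i:i + batch_size]))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    # -- parameters --------------------------------------------------------

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    def _batchnorm_layers(self) -> list[nn.BatchNorm]:
        out = []
        for layer in self.layers:
            if isinstance(layer, MSFEBlock):
                out.extend(s for s in layer._sublayers()
                           if isinstance(s, nn.BatchNorm))
            elif isinstance(layer, nn.BatchNorm):
                out.append(layer)
        return out

    def reestimate_bn_statistics(self, x: np.ndarray,
                                 batch_size: int = 32) -> None:
        """Replace every batch-norm layer's inference statistics with the
        exact average of the batch statistics of ``x`` under the current
        weights.

        An exponential moving average trails the weights by roughly
        1/(1-momentum) optimizer steps; with few steps per epoch that lag
        leaves inference-mode normalization visibly stale, so the
        training loop refreshes the statistics this way before each
        validation pass (the cumulative average is obtained by setting
        the EMA momentum of batch i to i/(i+1))."""
        x = self._prepare(x)
        bns = self._batchnorm_layers()
        saved_momentum = [bn.momentum for bn in bns]
        for bn in bns:
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 0.0
        try:
            n_batches = 0
            for start in range(0, len(x), batch_size):
                for bn in bns:
                    bn.momentum = n_batches / (n_batches + 1.0)
                h = x[start:start + batch_size]
                for layer in self.layers:
                    if isinstance(layer, nn.Flatten):
                        break  # statistics live in the conv stack only
                    h = layer.forward(h, training=True, cache=False)
                n_batches += 1
        finally:
            for bn, m in zip(bns, saved_momentum):
                bn.momentum = m

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for key, val in layer.params().items():
                out[f"{layer.name}/{key}" if "/" not in key else key] = val
        return out

    def param_grad_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers:
            p, g = layer.params(), layer.grads()
            for key in p:
                pairs.append((p[key], g[key]))
        return pairs

    def named_state(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers:
            for key, val in layer.state().items():
                out[f"{layer.name}/{key}" if "/" not in key else key] = val
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        """Copy of every trainable parameter and state buffer."""
        out = {f"param/{k}": v.copy() for k, v in self.named_params().items()}
        out.update({f"state/{k}": v.copy() for k, v in self.named_state().items()})
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        state = self.named_state()
        for key, val in weights.items():
            kind, _, name = key.partition("/")
            target = params if kind == "param" else state
            if name not in target:
                raise KeyError(f"unknown weight {key!r}")
            if target[name].shape != val.shape:
                raise ValueError(f"shape mismatch for {key!r}")
            target[name][...] = val


def count_trainable_parameters(model: Model) -> int:
    """Total element count over conv weights/biases, BN scales/shifts and
    dense weights/biases (running statistics excluded)."""
    return int(sum(p.size for p in model.named_params().values()))


def build_model(config: ArchitectureConfig, seed: int = 0,
                dtype=np.float32) -> Model:
    """Instantiate the network described by ``config``.

    Deterministic given ``seed``: the weight-initialization stream is a
    single seeded generator consumed in fixed layer order.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    channels = config.in_channels
    extent = config.input_size
    for idx, stage in enumerate(config.stages, start=1):
        name = f"stage{idx}"
        if isinstance(stage, MSFEBlockSpec):
            layers.extend(build_msfe_block(stage, channels, rng, name=name,
                                           dtype=dtype))
        elif isinstance(stage, ConvStageSpec):
            layers.append(nn.Conv2D(channels, stage.filters, stage.kernel_size,
                                    f"{name}.conv", rng, dtype=dtype))
            layers.append(nn.BatchNorm(stage.filters, f"{name}.bn", dtype=dtype))
            layers.append(nn.ReLU(f"{name}.relu"))
            layers.append(nn.MaxPool2x2(f"{name}.pool"))
        else:
            raise ConfigError(f"unknown stage spec {stage!r}")
        channels = stage.out_channels
        extent //= 2
    layers.append(nn.Flatten("flatten"))
    n_in = extent * extent * channels
    head = config.head
    for hidx, width in enumerate(head.hidden, start=1):
        layers.append(nn.Dense(n_in, width, f"fc{hidx}", rng, l2=head.l2,
                               dtype=dtype))
        layers.append(nn.ReLU(f"fc{hidx}.relu"))
        layers.append(nn.Dropout(head.dropout, f"fc{hidx}.dropout"))
        n_in = width
    layers.append(nn.Dense(n_in, config.n_classes, "logits", rng, l2=head.l2,
                           dtype=dtype))
    return Model(config, layers, dtype=dtype)


# ---------------------------------------------------------------------------
# Config and checkpoint I/O
# ---------------------------------------------------------------------------

def config_to_dict(config: ArchitectureConfig) -> dict:
    stages = []
    for stage in config.stages:
        if isinstance(stage, MSFEBlockSpec):
            stages.append({"type": "msfe", "f1": stage.f1, "f3": stage.f3,
                           "f5": stage.f5})
        else:
            stages.append({"type": "conv", "filters": stage.filters,
                           "kernel_size": stage.kernel_size})
    return {
        "input_size": config.input_size,
        "in_channels": config.in_channels,
        "n_classes": config.n_classes,
        "stages": stages,
        "head": {"hidden": list(config.head.hidden),
                 "dropout": config.head.dropout,
                 "l2": config.head.l2},
    }


def config_from_dict(doc: dict) -> ArchitectureConfig:
    stages = []
    for entry in doc["stages"]:
        kind = entry.get("type")
        if kind == "msfe":
            stages.append(MSFEBlockSpec(entry["f1"], entry["f3"], entry["f5"]))
        elif kind == "conv":
            stages.append(ConvStageSpec(entry["filters"],
                                        entry.get("kernel_size", 3)))
        else:
            raise ConfigError(f"unknown stage type {kind!r}")
    head_doc = doc.get("head", {})
    head = DenseHeadSpec(hidden=tuple(head_doc.get("hidden", (256, 128))),
                         dropout=head_doc.get("dropout", 0.1),
                         l2=head_doc.get("l2", 0.01))
    return ArchitectureConfig(stages=tuple(stages), head=head,
                              input_size=doc.get("input_size", 128),
                              in_channels=doc.get("in_channels", 1),
                              n_classes=doc.get("n_classes", 9))


def save_config(config: ArchitectureConfig, path: str | Path) -> None:
    path = Path(path)
    doc = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> ArchitectureConfig:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(doc)


def save_checkpoint(model: Model, path: str | Path) -> None:
    """Serialize parameters, BN statistics and the architecture config into
    a single ``.npz`` container."""
    arrays = model.get_weights()
    arrays["__config__"] = np.frombuffer(
        json.dumps(config_to_dict(model.config)).encode(), dtype=np.uint8)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path, dtype=np.float32) -> Model:
    with np.load(Path(path)) as data:
        doc = json.loads(bytes(data["__config__"]).decode())
        weights = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(config_from_dict(doc), seed=0, dtype=dtype)
    model.set_weights(weights)
    return model
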