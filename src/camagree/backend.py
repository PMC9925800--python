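"""Trainable CNN classifiers with the introspection hooks CAM methods need.

This is a compact CPU CNN engine built on a reverse-mode autodiff tape over
numpy arrays.  It exposes exactly the contract class-activation-map methods
require from a classifier:

* pre-softmax class scores ``Y^(c)`` for a batch of images,
* the activations ``A_k`` of any named convolutional layer (H, W, K),
* the gradient of a pre-softmax class score with respect to those
  activations, and
* class scores of channel-masked copies of an image (for Score-CAM).

Models are small directed acyclic graphs of standard layers (convolution,
ReLU, 2x2 max-pool, residual addition, branch concatenation, global average
pooling, dense head).  A registry provides three desk-scale architecture
families that preserve the structural distinctions of the large ImageNet
backbones used in CAM studies -- a plain deep stack, a residual network and
a parallel multi-branch network -- while remaining trainable in seconds on
one CPU core.  Arbitrary graphs (e.g. hand-weighted toy networks for
analytic oracles) can be assembled with :class:`GraphBuilder`.

All computation is float64 and fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ContractError, TrainingError

__all__ = [
    "Var",
    "GraphBuilder",
    "BackendModel",
    "TrainConfig",
    "TrainResult",
    "ARCHITECTURES",
    "build_model",
    "train",
    "evaluate_accuracy",
]


# ---------------------------------------------------------------------------
# Reverse-mode autodiff tape
# ---------------------------------------------------------------------------

class Var:
    """A node on the autodiff tape: an array value plus a backward closure."""

    __slots__ = ("data", "grad", "parents", "bwd")

    def __init__(self, data, parents=(), bwd=None):
        d = np.asarray(data)
        if d.dtype not in (np.float32, np.float64):
            d = d.astype(np.float64)
        self.data = d
        self.grad = None
        self.parents = parents
        self.bwd = bwd  # callable(grad_out) -> tuple of parent gradients


def backward(root: Var, seed: np.ndarray) -> None:
    """Accumulate gradients of ``seed . root`` into every ancestor's ``grad``."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        v, processed = stack.pop()
        if processed:
            topo.append(v)
            continue
        if id(v) in seen:
            continue
        seen.add(id(v))
        stack.append((v, True))
        for p in v.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.asarray(seed, dtype=root.data.dtype)
    for v in reversed(topo):
        if v.bwd is None or v.grad is None:
            continue
        for p, g in zip(v.parents, v.bwd(v.grad)):
            p.grad = g if p.grad is None else p.grad + g


# ---------------------------------------------------------------------------
# Differentiable ops (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, H*W) patches for 'same' convolution."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = xp.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2, s3)
    )
    return windows.reshape(n, c * kh * kw, ho * wo)


def _col2im(cols: np.ndarray, xshape: tuple, kh: int, kw: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = hp - kh + 1, wp - kw + 1
    acc = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    c6 = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            acc[:, :, i : i + ho, j : j + wo] += c6[:, :, i, j]
    return acc[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Var, w: Var, b: Var) -> Var:
    """'Same' convolution: x (N,C,H,W) with kernels w (K,C,kh,kw), bias b (K,)."""
    kout, cin, kh, kw = w.data.shape
    pad = (kh - 1) // 2
    n, c, h, wd = x.data.shape
    cols = _im2col(x.data, kh, kw, pad)  # (N, C*kh*kw, H*W)
    w2 = w.data.reshape(kout, -1)
    out = np.matmul(w2, cols).reshape(n, kout, h, wd) + b.data.reshape(1, -1, 1, 1)

    def bwd(go):
        go2 = go.reshape(n, kout, h * wd)
        dw = np.tensordot(go2, cols, axes=([0, 2], [0, 2])).reshape(w.data.shape)
        db = go.sum(axis=(0, 2, 3))
        dcols = np.matmul(w2.T, go2)
        dx = _col2im(dcols, x.data.shape, kh, kw, pad)
        return dx, dw, db

    return Var(out, (x, w, b), bwd)


def relu(x: Var) -> Var:
    mask = x.data > 0
    return Var(x.data * mask, (x,), lambda go: (go * mask,))


def maxpool2(x: Var) -> Var:
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    r = (
        x.data[:, :, : ho * 2, : wo * 2]
        .reshape(n, c, ho, 2, wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, 4)
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(go):
        dr = np.zeros((n, c, ho, wo, 4), dtype=go.dtype)
        np.put_along_axis(dr, idx[..., None], go[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : ho * 2, : wo * 2] = (
            dr.reshape(n, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * 2, wo * 2)
        )
        return (dx,)

    return Var(out, (x,), bwd)


def global_avg_pool(x: Var) -> Var:
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(go):
        return (np.broadcast_to(go[:, :, None, None] / (h * w), x.data.shape).copy(),)

    return Var(out, (x,), bwd)


def batchnorm2d(x: Var, gamma: Var, beta: Var, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool,
                momentum: float = 0.9, eps: float = 1e-5) -> Var:
    """Per-channel batch normalisation over (N, H, W).

    In training mode batch statistics are used and the running statistics
    are updated in place; in eval mode the transform is a fixed affine map,
    so CAM gradients through it are deterministic.
    """
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mu, var = running_mean, running_var
    ivstd = 1.0 / np.sqrt(var + eps)
    xc = x.data - mu[None, :, None, None]
    xhat = xc * ivstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    m = n * h * w

    def bwd(go):
        dgamma = (go * xhat).sum(axis=(0, 2, 3))
        dbeta = go.sum(axis=(0, 2, 3))
        dxhat = go * gamma.data[None, :, None, None]
        if training:
            iv = ivstd[None, :, None, None]
            dvar = (dxhat * xc * -0.5 * iv ** 3).sum(axis=(0, 2, 3))
            dmu = (-(dxhat * iv).sum(axis=(0, 2, 3))
                   + dvar * (-2.0 * xc.mean(axis=(0, 2, 3))))
            dx = (dxhat * iv
                  + dvar[None, :, None, None] * 2.0 * xc / m
                  + dmu[None, :, None, None] / m)
        else:
            dx = dxhat * ivstd[None, :, None, None]
        return dx, dgamma, dbeta

    return Var(out, (x, gamma, beta), bwd)


def flatten(x: Var) -> Var:
    shape = x.data.shape
    out = x.data.reshape(shape[0], -1)
    return Var(out, (x,), lambda go: (go.reshape(shape),))


def dense(x: Var, w: Var, b: Var) -> Var:
    out = x.data @ w.data + b.data

    def bwd(go):
        return go @ w.data.T, x.data.T @ go, go.sum(axis=0)

    return Var(out, (x, w, b), bwd)


def add(a: Var, b: Var) -> Var:
    return Var(a.data + b.data, (a, b), lambda go: (go, go))


def concat(xs: list[Var]) -> Var:
    sizes = [v.data.shape[1] for v in xs]
    out = np.concatenate([v.data for v in xs], axis=1)

    def bwd(go):
        grads, at = [], 0
        for s in sizes:
            grads.append(go[:, at : at + s])
            at += s
        return tuple(grads)

    return Var(out, tuple(xs), bwd)


# ---------------------------------------------------------------------------
# Model graphs
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str
    op: str           # input | conv | relu | pool | gap | dense | add | concat
    inputs: list      # predecessor node names
    params: list      # parameter keys in the model's param dict


class GraphBuilder:
    """Assemble a layer DAG with named nodes and He-initialised parameters."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.rng = rng or np.random.default_rng(0)
        self.nodes: list[_Node] = [_Node("input", "input", [], [])]
        self.params: dict[str, np.ndarray] = {}
        self._channels: dict[str, int] = {"input": 1}
        self.conv_layers: list[str] = []

    def _register(self, node: _Node, channels: int) -> str:
        self.nodes.append(node)
        self._channels[node.name] = channels
        return node.name

    def conv(self, name, src, cout, k=3, weights=None, bias=None):
        cin = self._channels[src]
        if weights is None:
            fan_in = cin * k * k
            weights = self.rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k))
        if bias is None:
            bias = np.zeros(cout)
        self.params[name + ".w"] = np.asarray(weights, dtype=np.float64)
        self.params[name + ".b"] = np.asarray(bias, dtype=np.float64)
        self.conv_layers.append(name)
        return self._register(_Node(name, "conv", [src], [name + ".w", name + ".b"]), cout)

    def bn(self, name, src):
        c = self._channels[src]
        self.params[name + ".gamma"] = np.ones(c)
        self.params[name + ".beta"] = np.zeros(c)
        self.params[name + ".rm"] = np.zeros(c)
        self.params[name + ".rv"] = np.ones(c)
        return self._register(
            _Node(name, "bn", [src],
                  [name + ".gamma", name + ".beta", name + ".rm", name + ".rv"]), c)

    def relu(self, name, src):
        return self._register(_Node(name, "relu", [src], []), self._channels[src])

    def pool(self, name, src):
        return self._register(_Node(name, "pool", [src], []), self._channels[src])

    def gap(self, name, src):
        return self._register(_Node(name, "gap", [src], []), self._channels[src])

    def flatten(self, name, src, spatial_size):
        c = self._channels[src] * spatial_size
        return self._register(_Node(name, "flatten", [src], []), c)

    def dense(self, name, src, cout, weights=None, bias=None):
        cin = self._channels[src]
        if weights is None:
            weights = self.rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout))
        if bias is None:
            bias = np.zeros(cout)
        self.params[name + ".w"] = np.asarray(weights, dtype=np.float64)
        self.params[name + ".b"] = np.asarray(bias, dtype=np.float64)
        return self._register(_Node(name, "dense", [src], [name + ".w", name + ".b"]), cout)

    def add(self, name, a, b):
        return self._register(_Node(name, "add", [a, b], []), self._channels[a])

    def concat(self, name, srcs):
        total = sum(self._channels[s] for s in srcs)
        return self._register(_Node(name, "concat", list(srcs), []), total)

    def build(self, architecture_id, output, stage_last_convs=None, n_classes=2):
        return BackendModel(
            architecture_id=architecture_id,
            nodes=self.nodes,
            params=self.params,
            output=output,
            conv_layers=list(self.conv_layers),
            stage_last_convs=stage_last_convs or list(self.conv_layers),
            n_classes=n_classes,
        )


@dataclass
class BackendModel:
    """A CNN classifier graph with named layers and pre-softmax score output.

    ``stage_last_convs`` lists the last convolution of each spatial-resolution
    stage (shallow to deep); it is the default multi-layer set for Layer-CAM.
    """

    architecture_id: str
    nodes: list
    params: dict
    output: str
    conv_layers: list
    stage_last_convs: list
    n_classes: int = 2

    # -- forward -----------------------------------------------------------
    def forward_vars(self, images: np.ndarray, override: dict | None = None,
                     training: bool = False) -> dict:
        """Run the graph on images (N,H,W) or (N,C,H,W); return name -> Var.

        ``override`` maps a node name to an array that replaces that node's
        output (as a fresh tape leaf), which makes it possible both to inject
        perturbed activations and to read gradients at that node.
        """
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4:
            raise ContractError(f"expected (N,H,W) or (N,C,H,W) images, got {x.shape}")
        vars: dict[str, Var] = {}
        for node in self.nodes:
            if override is not None and node.name in override:
                vars[node.name] = Var(override[node.name])
                continue
            ins = [vars[i] for i in node.inputs]
            if node.op == "input":
                v = Var(x)
            elif node.op == "conv":
                v = conv2d(ins[0], Var(self.params[node.params[0]]), Var(self.params[node.params[1]]))
            elif node.op == "bn":
                v = batchnorm2d(ins[0], Var(self.params[node.params[0]]),
                                Var(self.params[node.params[1]]),
                                self.params[node.params[2]],
                                self.params[node.params[3]], training)
            elif node.op == "relu":
                v = relu(ins[0])
            elif node.op == "pool":
                v = maxpool2(ins[0])
            elif node.op == "gap":
                v = global_avg_pool(ins[0])
            elif node.op == "flatten":
                v = flatten(ins[0])
            elif node.op == "dense":
                v = dense(ins[0], Var(self.params[node.params[0]]), Var(self.params[node.params[1]]))
            elif node.op == "add":
                v = add(ins[0], ins[1])
            elif node.op == "concat":
                v = concat(ins)
            else:  # pragma: no cover - graph construction guards this
                raise ContractError(f"unknown op {node.op!r}")
            vars[node.name] = v
        return vars

    # -- public contract ---------------------------------------------------
    @property
    def dtype(self):
        return next(iter(self.params.values())).dtype

    def astype(self, dtype) -> "BackendModel":
        """Convert all parameters in place (e.g. float32 for faster training)."""
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)
        return self

    @property
    def last_conv_layer(self) -> str:
        return self.conv_layers[-1]

    def layer_var(self, layer: str) -> None:
        if layer not in {n.name for n in self.nodes}:
            raise ContractError(f"unknown layer {layer!r}")

    def scores(self, images: np.ndarray, override: dict | None = None) -> np.ndarray:
        """Pre-softmax class scores, shape (N, n_classes)."""
        return self.forward_vars(images, override)[self.output].data

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.scores(images).argmax(axis=1)

    def activations(self, image: np.ndarray, layer: str | None = None) -> np.ndarray:
        """Activations A of ``layer`` for one image, shape (H, W, K)."""
        layer = layer or self.last_conv_layer
        self.layer_var(layer)
        v = self.forward_vars(np.asarray(image)[None])[layer]
        return np.transpose(v.data[0], (1, 2, 0))

    def class_gradient(
        self, image: np.ndarray, layer: str | None = None, class_index: int = 1
    ) -> np.ndarray:
        """Gradient of the pre-softmax score Y^(c) w.r.t. A, shape (H, W, K)."""
        layer = layer or self.last_conv_layer
        self.layer_var(layer)
        if not 0 <= class_index < self.n_classes:
            raise ContractError(f"class_index {class_index} out of range")
        vars = self.forward_vars(np.asarray(image)[None])
        seed = np.zeros_like(vars[self.output].data)
        seed[0, class_index] = 1.0
        backward(vars[self.output], seed)
        g = vars[layer].grad
        if g is None:
            raise ContractError(f"no differentiable path from {layer!r} to the scores")
        return np.transpose(g[0], (1, 2, 0))

    def score_with_activation(
        self, image: np.ndarray, layer: str, activation_hwk: np.ndarray, class_index: int = 1
    ) -> float:
        """Class score when ``layer``'s output is replaced by the given (H,W,K) array."""
        a = np.transpose(np.asarray(activation_hwk, dtype=self.dtype), (2, 0, 1))[None]
        return float(self.scores(np.asarray(image)[None], override={layer: a})[0, class_index])

    def masked_scores(
        self, image: np.ndarray, masks: np.ndarray, class_index: int = 1
    ) -> np.ndarray:
        """Scores Y^(c) of the image element-wise multiplied by each mask.

        ``masks`` is (n_masks, H, W) with values in [0, 1] at input resolution.
        """
        image = np.asarray(image, dtype=np.float64)
        masks = np.asarray(masks, dtype=np.float64)
        if masks.ndim != 3 or masks.shape[1:] != image.shape:
            raise ContractError(
                f"masks {masks.shape} do not match image {image.shape} at input resolution"
            )
        return self.scores(image[None] * masks)[:, class_index]

    # -- serialization -----------------------------------------------------
    def describe(self) -> dict:
        return {
            "architecture_id": self.architecture_id,
            "n_classes": self.n_classes,
            "output": self.output,
            "conv_layers": self.conv_layers,
            "stage_last_convs": self.stage_last_convs,
            "nodes": [
                {"name": n.name, "op": n.op, "inputs": n.inputs, "params": n.params}
                for n in self.nodes
            ],
        }

    def save(self, stem) -> None:
        """Write ``<stem>.npz`` (weights) and ``<stem>.json`` (architecture)."""
        stem = str(stem)
        np.savez(stem + ".npz", **self.params)
        with open(stem + ".json", "w") as fh:
            json.dump(self.describe(), fh, indent=2)

    @classmethod
    def load(cls, stem) -> "BackendModel":
        stem = str(stem)
        with open(stem + ".json") as fh:
            desc = json.load(fh)
        with np.load(stem + ".npz") as npz:
            params = {k: npz[k] for k in npz.files}
        nodes = [_Node(d["name"], d["op"], d["inputs"], d["params"]) for d in desc["nodes"]]
        return cls(
            architecture_id=desc["architecture_id"],
            nodes=nodes,
            params=params,
            output=desc["output"],
            conv_layers=desc["conv_layers"],
            stage_last_convs=desc["stage_last_convs"],
            n_classes=desc["n_classes"],
        )


# ---------------------------------------------------------------------------
# Architecture registry: three desk-scale families
# ---------------------------------------------------------------------------

def _build_plain(rng, width, n_classes):
    """Plain deep stack (VGG-family analogue)."""
    g = GraphBuilder(rng)
    h = g.conv("conv1", "input", width)
    h = g.bn("conv1_bn", h)
    h = g.relu("relu1", h)
    h = g.pool("pool1", h)
    h = g.conv("conv2", h, width * 2)
    h = g.bn("conv2_bn", h)
    h = g.relu("relu2", h)
    h = g.pool("pool2", h)
    h = g.conv("conv3", h, width * 2)
    h = g.bn("conv3_bn", h)
    h = g.relu("relu3", h)
    h = g.gap("gap", h)
    out = g.dense("fc", h, n_classes)
    return g.build("plain", out, stage_last_convs=["conv1", "conv2", "conv3"],
                   n_classes=n_classes)


def _build_residual(rng, width, n_classes):
    """Residual network analogue: one identity-skip block per stage."""
    g = GraphBuilder(rng)
    h = g.conv("conv1", "input", width)
    h = g.bn("conv1_bn", h)
    h = g.relu("relu1", h)
    h = g.pool("pool1", h)
    b = g.conv("res1a", h, width)
    b = g.bn("res1a_bn", b)
    b = g.relu("res1a_relu", b)
    b = g.conv("res1b", b, width)
    b = g.bn("res1b_bn", b)
    h = g.add("add1", h, b)
    h = g.relu("relu2", h)
    h = g.pool("pool2", h)
    h = g.conv("conv3", h, width * 2)
    h = g.bn("conv3_bn", h)
    h = g.relu("relu3", h)
    h = g.gap("gap", h)
    out = g.dense("fc", h, n_classes)
    return g.build("residual", out, stage_last_convs=["conv1", "res1b", "conv3"],
                   n_classes=n_classes)


def _build_branch(rng, width, n_classes):
    """Parallel multi-scale branches (inception-family analogue)."""
    g = GraphBuilder(rng)
    h = g.conv("conv1", "input", width)
    h = g.bn("conv1_bn", h)
    h = g.relu("relu1", h)
    h = g.pool("pool1", h)
    b1 = g.conv("branch1x1", h, width, k=1)
    b1 = g.bn("branch1x1_bn", b1)
    b2 = g.conv("branch3x3", h, width, k=3)
    b2 = g.bn("branch3x3_bn", b2)
    b3 = g.conv("branch5x5", h, width, k=5)
    b3 = g.bn("branch5x5_bn", b3)
    h = g.concat("mix", [b1, b2, b3])
    h = g.relu("relu2", h)
    h = g.pool("pool2", h)
    h = g.conv("conv3", h, width * 2)
    h = g.bn("conv3_bn", h)
    h = g.relu("relu3", h)
    h = g.gap("gap", h)
    out = g.dense("fc", h, n_classes)
    return g.build("branch", out, stage_last_convs=["conv1", "branch3x3", "conv3"],
                   n_classes=n_classes)


ARCHITECTURES = {
    "plain": _build_plain,
    "residual": _build_residual,
    "branch": _build_branch,
}


def build_model(architecture_id: str, seed: int = 0, width: int = 12,
                n_classes: int = 2) -> BackendModel:
    """Instantiate a registry architecture with seeded He initialisation."""
    if architecture_id not in ARCHITECTURES:
        raise ConfigurationError(
            f"unknown architecture {architecture_id!r}; choose from {sorted(ARCHITECTURES)}"
        )
    rng = np.random.default_rng(seed)
    return ARCHITECTURES[architecture_id](rng, width, n_classes)


# ---------------------------------------------------------------------------
# Training (SGD + early stopping)
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Stochastic-gradient-descent settings.

    ``early_stopping_patience`` counts epochs without validation-accuracy
    improvement before training stops and the best weights are restored.
    """

    learning_rate: float = 5e-3
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 120
    early_stopping_patience: int = 25

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.early_stopping_patience >= self.max_epochs:
            raise ConfigurationError("patience must be < max_epochs")


@dataclass
class TrainResult:
    model: BackendModel
    history: list = field(default_factory=list)   # dicts: epoch, loss, train/val acc
    best_epoch: int = -1
    best_val_accuracy: float = 0.0


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def evaluate_accuracy(model: BackendModel, images: np.ndarray, labels: np.ndarray,
                      batch_size: int = 64) -> float:
    labels = np.asarray(labels)
    hits = 0
    for at in range(0, len(labels), batch_size):
        hits += int((model.predict(images[at : at + batch_size]) == labels[at : at + batch_size]).sum())
    return hits / len(labels)


def train(model: BackendModel, train_set, val_set, cfg: TrainConfig | None = None,
          seed: int = 0) -> TrainResult:
    """Train with SGD on softmax cross-entropy; deterministic for a fixed seed.

    ``train_set``/``val_set`` are ``(images (N,H,W), labels (N,))`` pairs.
    Raises :class:`TrainingError` (with the trace so far) if the loss
    becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    dtype = model.dtype
    xtr, ytr = np.asarray(train_set[0], dtype=dtype), np.asarray(train_set[1])
    xva, yva = np.asarray(val_set[0], dtype=dtype), np.asarray(val_set[1])
    if len(xtr) == 0 or len(xva) == 0:
        raise ContractError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(seed)
    result = TrainResult(model=model)
    best_params = {k: v.copy() for k, v in model.params.items()}
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xtr))
        losses = []
        hits = 0
        for at in range(0, len(order), cfg.batch_size):
            idx = order[at : at + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            vars = model.forward_vars(xb, training=True)
            logits = vars[model.output]
            probs = _softmax(logits.data)
            n = len(idx)
            hits += int((logits.data.argmax(axis=1) == yb).sum())
            loss = -np.mean(np.log(probs[np.arange(n), yb] + 1e-300))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}", history=result.history
                )
            losses.append(loss)
            dlogits = probs.copy()
            dlogits[np.arange(n), yb] -= 1.0
            dlogits /= n
            # gradients flow to parameter leaf Vars created in forward_vars
            param_vars = _collect_param_vars(model, vars)
            backward(logits, dlogits)
            for key, pv in param_vars.items():
                if pv.grad is not None:
                    velocity[key] = (cfg.momentum * velocity[key]
                                     - cfg.learning_rate * pv.grad)
                    model.params[key] += velocity[key]
        tr_acc = hits / len(order)   # batch-wise accuracy during the epoch
        va_acc = evaluate_accuracy(model, xva, yva)
        result.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "train_accuracy": tr_acc, "val_accuracy": va_acc}
        )
        if va_acc > result.best_val_accuracy:
            result.best_val_accuracy = va_acc
            result.best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale > cfg.early_stopping_patience:
                break
    model.params.update(best_params)
    return result


def _collect_param_vars(model: BackendModel, vars: dict) -> dict:
    """Map param key -> the leaf Var holding it in this forward pass."""
    out = {}
    for node in model.nodes:
        if node.params:
            v = vars[node.name]
            # conv/dense parents are (input, w, b)
            out[node.params[0]] = v.parents[1]
            out[node.params[1]] = v.parents[2]
    return out
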