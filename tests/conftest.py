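"""Shared fixtures: small synthetic datasets and hand-weighted toy networks."""

import numpy as np
import pytest

import camagree
from camagree import backend, pipeline, preprocess
from camagree.backend import GraphBuilder


@pytest.fixture(scope="session")
def tiny_config():
    return camagree.GeneratorConfig(
        image_size=32,
        n_samples_per_group=4,
        slices_per_sample=2,
        treatment_levels=(0.9,),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return camagree.generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_dataset):
    """A small classifier trained briefly on the tiny dataset -- enough to
    produce informative, non-degenerate heatmaps for contract tests."""
    split = preprocess.split_by_sample(tiny_dataset, seed=7)
    parts = pipeline._partition_arrays(tiny_dataset, split)
    model = backend.build_model("plain", seed=7, width=4).astype(np.float32)
    backend.train(model, parts["train"], parts["val"],
                  backend.TrainConfig(max_epochs=25, early_stopping_patience=24),
                  seed=7)
    return model


def make_gap_linear_model(conv_w, dense_w):
    """input -> conv -> global-average-pool -> dense, with given weights.

    The classic CAM projection is exact for this architecture:
    CAM_c(x, y) = sum_k dense_w[k, c] * A_k(x, y).
    """
    conv_w = np.asarray(conv_w, dtype=np.float64)
    dense_w = np.asarray(dense_w, dtype=np.float64)
    k = conv_w.shape[0]
    g = GraphBuilder(np.random.default_rng(0))
    h = g.conv("conv1", "input", k, k=conv_w.shape[-1], weights=conv_w,
               bias=np.zeros(k))
    h = g.gap("gap", h)
    out = g.dense("fc", h, dense_w.shape[1], weights=dense_w,
                  bias=np.zeros(dense_w.shape[1]))
    return g.build("toy_gap_linear", out)


def make_random_small_net(seed, in_size=8, channels=(3, 4)):
    """A random <=10^3-parameter conv net for finite-difference oracles."""
    rng = np.random.default_rng(seed)
    g = GraphBuilder(rng)
    h = g.conv("conv1", "input", channels[0])
    h = g.relu("relu1", h)
    h = g.pool("pool1", h)
    h = g.conv("conv2", h, channels[1])
    h = g.relu("relu2", h)
    h = g.gap("gap", h)
    out = g.dense("fc", h, 2)
    model = g.build("toy_random", out)
    assert sum(p.size for p in model.params.values()) <= 1000
    return model


def exp_score_gradient(model, image, layer, activation_hwk, class_index=1):
    """Exact backprop gradient of exp(Y^(c)) w.r.t. an injected activation.

    Returns ``(exp_score, grad)`` with grad shaped (H, W, K); used as the
    base of higher-order finite-difference oracles.
    """
    a = np.transpose(np.asarray(activation_hwk, dtype=np.float64), (2, 0, 1))[None]
    vars = model.forward_vars(np.asarray(image)[None], override={layer: a})
    out = vars[model.output]
    seed = np.zeros_like(out.data)
    seed[0, class_index] = 1.0
    backend.backward(out, seed)
    score = float(out.data[0, class_index])
    g = np.transpose(vars[layer].grad[0], (1, 2, 0))
    return np.exp(score), np.exp(score) * g


@pytest.fixture
def rng():
    return np.random.default_rng(42)
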