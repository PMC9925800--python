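"""Five class-activation-map methods plus shared post-processing.

All methods consume a trained :class:`~camagree.backend.BackendModel`, one
2-D grayscale image and a class index (the damaged class, y=1, by default)
and produce a :class:`CamHeatmap`: a map at input resolution, min-max
normalised to [0, 1], where higher values mark regions more discriminative
for the class.

Implemented methods
-------------------
* **Grad-CAM** -- channel weights are the global average of the pre-softmax
  class-score gradient over the layer's spatial extent; map is
  ReLU(sum_k w_k A_k).
* **Grad-CAM++** -- channel weights are a location-weighted average of the
  *positive* gradients, with weights alpha from the closed form
  ``alpha = g^2 / (2 g^2 + sum_ab A(a,b) g^3)`` (elementwise in g, the
  gradient of the exponentialised pre-softmax score for a piecewise-linear
  network; 0/0 -> 0), normalised per channel over positive-gradient
  locations so that spatially constant positive gradients recover Grad-CAM
  exactly.
* **Score-CAM** -- gradient-free: each channel's activation map is
  bilinearly upsampled, min-max normalised, used to mask the input image,
  and the channel weight is the softmax over channels of the masked images'
  pre-softmax class scores.
* **Faster Score-CAM** -- Score-CAM restricted to the ``top_n`` channels
  with the highest spatial activation variance (ties broken by lowest
  channel index).
* **Layer-CAM** -- per-location weights ReLU(g) (in "paper" mode g is the
  gradient's deviation from its spatial mean; "classic" mode uses the raw
  gradient), per-layer maps rescaled by tanh(gamma * M / max M) after
  upsampling, multiple layers fused by element-wise maximum (or mean).

Binarisation thresholds a normalised heatmap at t_CAM (values >= t_CAM are
damage), optionally restricted to a foreground mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .backend import BackendModel
from .exceptions import ContractError, DomainError

__all__ = [
    "CamHeatmap",
    "grad_cam",
    "grad_cam_pp",
    "gradcam_pp_alpha",
    "score_cam",
    "score_cam_weights",
    "faster_score_cam",
    "top_variance_channels",
    "layer_cam",
    "layer_cam_prenorm",
    "binarize",
    "CAM_METHODS",
    "compute_cam",
]


@dataclass
class CamHeatmap:
    """A per-pixel relevance map in [0, 1] at input resolution."""

    values: np.ndarray
    method: str
    model: str
    layer: object          # layer name, or tuple of names for Layer-CAM
    class_index: int


# ---------------------------------------------------------------------------
# Shared post-processing
# ---------------------------------------------------------------------------

def _upsample(map2d: np.ndarray, shape) -> np.ndarray:
    if map2d.shape == tuple(shape):
        return np.asarray(map2d, dtype=float)
    return resize(np.asarray(map2d, dtype=float), shape, order=1,
                  mode="edge", anti_aliasing=False, preserve_range=True)


def normalize_heatmap(values: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; an identically-zero map stays all zeros,
    a non-zero constant map becomes all ones (its maximum)."""
    values = np.asarray(values, dtype=float)
    hi, lo = values.max(), values.min()
    if hi == 0 and lo == 0:
        return np.zeros_like(values)
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def _finish(raw_small, image, method, model, layer, class_index) -> CamHeatmap:
    up = _upsample(np.maximum(raw_small, 0.0), np.asarray(image).shape)
    return CamHeatmap(normalize_heatmap(up), method, model.architecture_id,
                      layer, class_index)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def grad_cam(model: BackendModel, image, layer: str | None = None,
             class_index: int = 1) -> CamHeatmap:
    layer = layer or model.last_conv_layer
    a = model.activations(image, layer)              # (H, W, K)
    g = model.class_gradient(image, layer, class_index)
    if a.size == 0:
        raise ContractError("zero-size layer")
    w = g.mean(axis=(0, 1))                          # GAP of gradients
    raw = (a * w).sum(axis=-1)
    return _finish(raw, image, "gradcam", model, layer, class_index)


# ---------------------------------------------------------------------------
# Grad-CAM++
# ---------------------------------------------------------------------------

def gradcam_pp_alpha(a: np.ndarray, g: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Location weights alpha for Grad-CAM++ from activations and gradients.

    ``a`` and ``g`` are (H, W, K).  The closed form is exact for the true
    second/third derivatives of the exponentialised pre-softmax score of a
    piecewise-linear network (the common exponentials cancel).  With
    ``normalize`` the alphas of each channel are rescaled to sum to one over
    positive-gradient locations, which makes w_k a weighted average of the
    positive gradients and recovers the plain gradient average when the
    gradient field is spatially constant.
    """
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + a.sum(axis=(0, 1), keepdims=True) * g3
    alpha = np.divide(g2, denom, out=np.zeros_like(g2), where=denom != 0)
    if normalize:
        pos = g > 0
        per_channel = (alpha * pos).sum(axis=(0, 1), keepdims=True)
        alpha = np.divide(alpha, per_channel, out=alpha,
                          where=per_channel != 0)
    return alpha


def grad_cam_pp(model: BackendModel, image, layer: str | None = None,
                class_index: int = 1) -> CamHeatmap:
    layer = layer or model.last_conv_layer
    a = model.activations(image, layer)
    g = model.class_gradient(image, layer, class_index)
    alpha = gradcam_pp_alpha(a, g, normalize=True)
    w = (alpha * np.maximum(g, 0.0)).sum(axis=(0, 1))
    raw = (a * w).sum(axis=-1)
    return _finish(raw, image, "gradcampp", model, layer, class_index)


# ---------------------------------------------------------------------------
# Score-CAM and Faster Score-CAM
# ---------------------------------------------------------------------------

def _stable_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _score_cam_core(model, image, layer, class_index, channels):
    """Softmax channel weights over masked-input class scores + raw map."""
    image = np.asarray(image, dtype=float)
    a = model.activations(image, layer)              # (H, W, K)
    masks = []
    for k in channels:
        ak_up = _upsample(a[:, :, k], image.shape)
        hi, lo = ak_up.max(), ak_up.min()
        if hi == lo:
            masks.append(np.zeros_like(image))       # constant channel
        else:
            masks.append((ak_up - lo) / (hi - lo))
    scores = model.masked_scores(image, np.stack(masks), class_index)
    w = _stable_softmax(scores)
    raw = np.tensordot(a[:, :, channels], w, axes=([2], [0]))
    return w, raw


def score_cam_weights(model: BackendModel, image, layer: str | None = None,
                      class_index: int = 1) -> np.ndarray:
    """The softmax channel-weight vector (sums to 1 over channels)."""
    layer = layer or model.last_conv_layer
    k = model.activations(image, layer).shape[-1]
    w, _ = _score_cam_core(model, image, layer, class_index, list(range(k)))
    return w


def score_cam(model: BackendModel, image, layer: str | None = None,
              class_index: int = 1) -> CamHeatmap:
    layer = layer or model.last_conv_layer
    k = model.activations(image, layer).shape[-1]
    _, raw = _score_cam_core(model, image, layer, class_index, list(range(k)))
    return _finish(raw, image, "scorecam", model, layer, class_index)


def top_variance_channels(activations: np.ndarray, top_n: int) -> list:
    """Indices of the ``top_n`` channels by spatial variance (descending),
    ties broken by lowest channel index; all channels if K <= top_n."""
    k = activations.shape[-1]
    if k <= top_n:
        return list(range(k))
    var = activations.var(axis=(0, 1))
    order = np.lexsort((np.arange(k), -var))
    return sorted(order[:top_n].tolist())


def faster_score_cam(model: BackendModel, image, layer: str | None = None,
                     class_index: int = 1, top_n: int = 10) -> CamHeatmap:
    """Score-CAM on the ``top_n`` highest-spatial-variance channels only."""
    layer = layer or model.last_conv_layer
    a = model.activations(image, layer)
    channels = top_variance_channels(a, top_n)
    _, raw = _score_cam_core(model, image, layer, class_index, channels)
    return _finish(raw, image, "faster_scorecam", model, layer, class_index)


# ---------------------------------------------------------------------------
# Layer-CAM
# ---------------------------------------------------------------------------

def layer_cam_prenorm(model: BackendModel, image, layers=None,
                      class_index: int = 1, gamma: float = 2.0,
                      mode: str = "paper", fusion: str = "max") -> np.ndarray:
    """Fused Layer-CAM map *before* the final [0,1] normalisation.

    Whenever at least one layer has a non-zero map M, the fused map's
    maximum equals tanh(gamma).
    """
    if mode not in ("paper", "classic"):
        raise DomainError("mode must be 'paper' or 'classic'")
    if fusion not in ("max", "mean"):
        raise DomainError("fusion must be 'max' or 'mean'")
    layers = list(layers) if layers is not None else list(model.stage_last_convs)
    if not layers:
        raise ContractError("layer_cam needs at least one layer")
    image = np.asarray(image, dtype=float)
    per_layer = []
    for layer in layers:
        a = model.activations(image, layer)
        g = model.class_gradient(image, layer, class_index)
        if mode == "paper":
            scale = np.abs(g).max()
            g = g - g.mean(axis=(0, 1), keepdims=True)
            # a spatially constant gradient must yield an exactly zero map;
            # suppress float residue of the mean subtraction
            g[np.abs(g) <= 1e-9 * scale] = 0.0
        w = np.maximum(g, 0.0)
        m = np.maximum((w * a).sum(axis=-1), 0.0)
        m_up = _upsample(m, image.shape)
        m_up = np.maximum(m_up, 0.0)
        top = m_up.max()
        per_layer.append(np.tanh(gamma * m_up / top) if top > 0
                         else np.zeros_like(m_up))
    stack = np.stack(per_layer)
    return stack.max(axis=0) if fusion == "max" else stack.mean(axis=0)


def layer_cam(model: BackendModel, image, layers=None, class_index: int = 1,
              gamma: float = 2.0, mode: str = "paper",
              fusion: str = "max") -> CamHeatmap:
    layers = list(layers) if layers is not None else list(model.stage_last_convs)
    fused = layer_cam_prenorm(model, image, layers, class_index, gamma, mode, fusion)
    return CamHeatmap(normalize_heatmap(fused), "layercam",
                      model.architecture_id, tuple(layers), class_index)


# ---------------------------------------------------------------------------
# Binarisation
# ---------------------------------------------------------------------------

def binarize(heatmap, t_cam: float, foreground: np.ndarray | None = None,
             strict: bool = False) -> np.ndarray:
    """Threshold a normalised heatmap into a 0/1 damage mask.

    Pixels with value >= t_cam (or > with ``strict``) are damage.  When a
    foreground mask is supplied the result is restricted to it.
    """
    if not 0.0 < t_cam < 1.0:
        raise DomainError("t_cam must lie strictly inside (0, 1)")
    values = heatmap.values if isinstance(heatmap, CamHeatmap) else np.asarray(heatmap)
    mask = (values > t_cam) if strict else (values >= t_cam)
    if foreground is not None:
        if foreground.shape != values.shape:
            raise ContractError("foreground mask shape mismatch")
        mask = mask & (foreground > 0)
    return mask.astype(np.uint8)


CAM_METHODS = {
    "gradcam": grad_cam,
    "gradcampp": grad_cam_pp,
    "scorecam": score_cam,
    "faster_scorecam": faster_score_cam,
    "layercam": layer_cam,
}


def compute_cam(method: str, model: BackendModel, image,
                class_index: int = 1, **kwargs) -> CamHeatmap:
    """Dispatch a CAM method by name."""
    if method not in CAM_METHODS:
        raise DomainError(f"unknown CAM method {method!r}; choose from {sorted(CAM_METHODS)}")
    return CAM_METHODS[method](model, image, class_index=class_index, **kwargs)
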