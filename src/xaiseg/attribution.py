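"""Attribution heatmaps: repurposing a classifier as a weak segmenter.

Each method asks the trained 2-class scorer *where* the evidence for the
tumour class sits in the input and returns a ``Heatmap`` — a 2D map
min-max-normalised to [0, 1].  Input-level methods (saliency, input x
gradient, guided backpropagation, occlusion, feature ablation) reduce
multi-channel attributions by the maximum of absolute values across
channels, which preserves thin high-attribution structures better than a
mean.  Grad-CAM works at a convolutional stage and is upsampled
bilinearly; guided Grad-CAM is the elementwise product of the guided
backpropagation and Grad-CAM maps before normalisation.

Normalisation rule: per-map min-max on absolute attributions; a map whose
raw attributions are all equal (e.g. a constant scorer) normalises to all
zeros.  This fixed [0, 1] scale is what makes a downstream absolute
threshold (0.35 by default in postprocessing) meaningful.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np
import pandas as pd

from .classifier import ClassifierHandle

__all__ = ["Heatmap", "OcclusionConfig", "LayerAttribution",
           "saliency", "input_x_gradient", "guided_backprop", "grad_cam",
           "guided_grad_cam", "occlusion", "feature_ablation",
           "layer_gradient_x_activation", "channel_heatmap",
           "neuron_gradient", "benchmark_methods", "heatmap_to_png"]


@dataclasses.dataclass(frozen=True)
class Heatmap:
    values: np.ndarray          # (H, W) in [0, 1]
    method: str
    target_class: int
    raw_range: tuple            # (min, max) of the pre-normalisation map


@dataclasses.dataclass(frozen=True)
class OcclusionConfig:
    window: tuple = (16, 16)
    stride: tuple = (8, 8)
    baseline: float = 0.0

    def validate(self):
        if min(self.window) < 1 or min(self.stride) < 1:
            raise ValueError("window and stride must be >= 1 in both dims")


@dataclasses.dataclass(frozen=True)
class LayerAttribution:
    channels: np.ndarray        # (K, h, w) raw per-channel maps
    layer: str
    selected_channel: int | None = None


# -- shared helpers ----------------------------------------------------------

def _reduce_channels(raw) -> np.ndarray:
    """|.| then max across channels -> non-negative (H, W) map."""
    raw = np.abs(np.asarray(raw, dtype=np.float64))
    return raw.max(axis=0) if raw.ndim == 3 else raw


def _normalise(raw2d, method, target) -> Heatmap:
    raw2d = np.asarray(raw2d, dtype=np.float64)
    lo, hi = float(raw2d.min()), float(raw2d.max())
    if hi == lo:
        values = np.zeros_like(raw2d)
    else:
        values = (raw2d - lo) / (hi - lo)
    return Heatmap(values=values, method=method, target_class=target,
                   raw_range=(lo, hi))


# -- gradient methods --------------------------------------------------------

def saliency(handle: ClassifierHandle, image, target: int) -> Heatmap:
    """|d score_target / d input|, channel-reduced and normalised."""
    g = handle.input_gradient(image, target)
    return _normalise(_reduce_channels(g), "saliency", target)


def input_x_gradient(handle: ClassifierHandle, image, target: int) -> Heatmap:
    """|input ⊙ gradient| — gradient scaled by the signal it acts on."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    g = handle.input_gradient(image, target)
    return _normalise(_reduce_channels(x * g), "input_x_gradient", target)


def guided_backprop(handle: ClassifierHandle, image, target: int) -> Heatmap:
    """Saliency with the guided rectifier rule: at every rectifier the
    backward pass keeps only positions whose forward pre-activation and
    incoming gradient are both strictly positive."""
    g = handle.input_gradient(image, target, guided=True)
    return _normalise(_reduce_channels(g), "guided_backprop", target)


def _grad_cam_raw(handle, image, target, layer):
    acts, grads = handle.layer_activations_and_gradients(image, target, layer)
    alpha = grads.mean(axis=(1, 2))                      # (K,)
    cam = np.einsum("k,khw->hw", alpha, acts)
    cam = np.maximum(cam, 0.0)                           # rectified
    from .io_formats import resize_image
    h, w = handle.input_size
    return resize_image(cam, (h, w), kind="bilinear")


def grad_cam(handle: ClassifierHandle, image, target: int,
             layer: str | None = None) -> Heatmap:
    """Class activation map: spatial-mean gradient weights per channel,
    weighted sum of activation maps, rectified, bilinearly upsampled."""
    layer = layer or handle.layer_names()[-1]
    cam = _grad_cam_raw(handle, image, target, layer)
    return _normalise(cam, "grad_cam", target)


def guided_grad_cam(handle: ClassifierHandle, image, target: int,
                    layer: str | None = None) -> Heatmap:
    """Elementwise product of the (pre-normalisation) guided backprop and
    Grad-CAM maps, then normalised — sharp edges gated by localisation."""
    layer = layer or handle.layer_names()[-1]
    gb = _reduce_channels(handle.input_gradient(image, target, guided=True))
    cam = _grad_cam_raw(handle, image, target, layer)
    return _normalise(gb * cam, "guided_grad_cam", target)


# -- perturbation methods ----------------------------------------------------

def occlusion_raw(handle: ClassifierHandle, image, target: int,
                  config: OcclusionConfig = OcclusionConfig()) -> np.ndarray:
    """Signed mean score-drop map before |.| and normalisation.

    Windows are placed row-major at stride offsets; a pixel covered by no
    placement attributes zero.
    """
    config.validate()
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    _, h, w = x.shape
    wh, ww = config.window
    sh, sw = config.stride
    if wh > h or ww > w:
        raise ValueError(f"window {config.window} larger than image "
                         f"({h}, {w})")
    handle._check_target(target)
    y0 = handle.forward(x)[target]
    total = np.zeros((h, w))
    count = np.zeros((h, w))
    for r in range(0, h - wh + 1, sh):
        for c in range(0, w - ww + 1, sw):
            xo = x.copy()
            xo[:, r:r + wh, c:c + ww] = config.baseline
            drop = y0 - handle.forward(xo)[target]
            total[r:r + wh, c:c + ww] += drop
            count[r:r + wh, c:c + ww] += 1
    return np.divide(total, count, out=np.zeros_like(total), where=count > 0)


def occlusion(handle: ClassifierHandle, image, target: int,
              config: OcclusionConfig = OcclusionConfig()) -> Heatmap:
    """Slide a baseline-filled window; attribute to each pixel the mean
    drop in the target score over all window placements covering it."""
    raw = occlusion_raw(handle, image, target, config)
    return _normalise(np.abs(raw), "occlusion", target)


def feature_ablation_raw(handle: ClassifierHandle, image, target: int,
                         groups, baseline: float = 0.0) -> np.ndarray:
    """Signed per-group score-drop map before |.| and normalisation."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    groups = np.asarray(groups)
    if groups.shape != x.shape[1:]:
        raise ValueError(f"groups shape {groups.shape} != image "
                         f"shape {x.shape[1:]}")
    labels = np.unique(groups)
    if labels.size == 0:
        raise ValueError("groups has no labels")
    handle._check_target(target)
    y0 = handle.forward(x)[target]
    raw = np.zeros(x.shape[1:])
    for g in labels:
        sel = groups == g
        xo = x.copy()
        xo[:, sel] = baseline
        raw[sel] = y0 - handle.forward(xo)[target]
    return raw


def feature_ablation(handle: ClassifierHandle, image, target: int,
                     groups, baseline: float = 0.0) -> Heatmap:
    """Occlusion generalised to arbitrary pixel groups: every pixel of a
    group receives the score drop from setting that group to baseline."""
    raw = feature_ablation_raw(handle, image, target, groups, baseline)
    return _normalise(np.abs(raw), "feature_ablation", target)


# -- layer / neuron methods --------------------------------------------------

def layer_gradient_x_activation(handle: ClassifierHandle, image, target: int,
                                layer: str) -> LayerAttribution:
    """Per-channel A_k ⊙ dscore/dA_k at the layer's native resolution.

    No automatic channel reduction: channel choice is explicit (the manual
    selection step of layer-level inspection), via ``channel_heatmap``.
    """
    acts, grads = handle.layer_activations_and_gradients(image, target, layer)
    return LayerAttribution(channels=acts * grads, layer=layer)


def channel_heatmap(attr: LayerAttribution, channel: int,
                    target: int = 1) -> Heatmap:
    """Select one channel of a layer attribution and normalise it."""
    k = attr.channels.shape[0]
    if not 0 <= channel < k:
        raise ValueError(f"channel {channel} outside [0, {k})")
    raw = np.abs(attr.channels[channel])
    hm = _normalise(raw, f"layer_gradient_x_activation[{attr.layer}:"
                         f"{channel}]", target)
    return hm


def neuron_gradient(handle: ClassifierHandle, image, neuron) -> Heatmap:
    """|d a_neuron / d input| for one internal unit, reduced/normalised
    like saliency.  ``neuron`` = (layer, channel, row, col), or
    ("output", class_index) for a head unit (then identical to saliency)."""
    g = handle.neuron_input_gradient(image, neuron)
    target = int(neuron[1]) if neuron[0] == "output" else -1
    return _normalise(_reduce_channels(g), "neuron_gradient", target)


# -- benchmarking ------------------------------------------------------------

def _method_registry(handle, image, target, layer, occ_config):
    layer = layer or handle.layer_names()[-1]
    groups = np.arange(np.prod(handle.input_size)).reshape(handle.input_size)
    return {
        "saliency": lambda: saliency(handle, image, target),
        "input_x_gradient": lambda: input_x_gradient(handle, image, target),
        "guided_backprop": lambda: guided_backprop(handle, image, target),
        "grad_cam": lambda: grad_cam(handle, image, target, layer),
        "guided_grad_cam": lambda: guided_grad_cam(handle, image, target,
                                                   layer),
        "occlusion": lambda: occlusion(handle, image, target, occ_config),
        "feature_ablation": lambda: feature_ablation(handle, image, target,
                                                     groups),
        "layer_gradient_x_activation": lambda: layer_gradient_x_activation(
            handle, image, target, layer),
        "neuron_gradient": lambda: neuron_gradient(
            handle, image, (layer, 0, 0, 0)),
    }


METHOD_NAMES = ("saliency", "input_x_gradient", "guided_backprop",
                "grad_cam", "guided_grad_cam", "occlusion",
                "feature_ablation", "layer_gradient_x_activation",
                "neuron_gradient")


def benchmark_methods(handle: ClassifierHandle, image, methods,
                      repeats: int = 3, target: int = 1,
                      layer: str | None = None,
                      occ_config: OcclusionConfig = OcclusionConfig()
                      ) -> pd.DataFrame:
    """Median wall-clock seconds per method, sorted ascending.

    Absolute numbers are hardware-dependent and are reported, never
    asserted.
    """
    if not methods:
        raise ValueError("empty method list")
    registry = _method_registry(handle, image, target, layer, occ_config)
    rows = []
    for name in methods:
        if name not in registry:
            raise ValueError(f"unknown method {name!r}; "
                             f"available: {sorted(registry)}")
        times = []
        for _ in range(repeats):
            t0 = time.perf_counter()
            registry[name]()
            times.append(time.perf_counter() - t0)
        rows.append({"method": name, "seconds": float(np.median(times))})
    return (pd.DataFrame(rows)
            .sort_values("seconds", ascending=True)
            .reset_index(drop=True))


def heatmap_to_png(heatmap: Heatmap, path) -> None:
    """Export as 8-bit grayscale PNG: value = round(255 * normalised)."""
    from .io_formats import write_image_u8
    write_image_u8(path, np.round(heatmap.values * 255).astype(np.uint8))
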