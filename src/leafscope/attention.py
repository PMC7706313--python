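"""Visualization IV: attention-map algorithms with layer targeting.

Eight input-aligned heatmap methods in three families:

* perturbation-based — occlusion analysis, superpixel linear-surrogate
  (LIME-style) explanation;
* gradient-based — vanilla saliency, integrated gradients, guided
  back-propagation, Grad-CAM (targetable at any spatial layer);
* reference-based — DeepLIFT (rescale rule against one healthy reference
  image), explanation map (forward-only, per-channel activation thresholds
  from a healthy reference batch, sum of the top-k normalized channels).

Every method returns an :class:`AttentionMap` whose ``values`` are min-max
normalized to [0, 1] (constant maps collapse to zero) and whose ``raw``
field retains the unnormalized, signed quantities for quantitative work.
``layer_scan`` runs Grad-CAM or the explanation map across a list of layers
to find the visualization-effective depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.segmentation import slic
from skimage.transform import resize

from .netcore import (DTYPE, PropagationRule, backward, class_logit_target,
                      run_forward, ConfigurationError)


@dataclass
class AttentionMap:
    """H x W heatmap aligned pixel-for-pixel to the input image."""

    values: np.ndarray
    raw: np.ndarray
    method: str
    target_class: int | None = None
    layer: str | None = None


def _normalize(raw):
    lo, hi = raw.min(), raw.max()
    if hi <= lo:
        return np.zeros_like(raw, dtype=float)
    return (raw - lo) / (hi - lo)


def _channel_max_abs(signal):
    return np.abs(signal).max(axis=-1)


def _upsample(map2d, shape):
    if map2d.shape == tuple(shape):
        return map2d
    return resize(map2d, shape, order=1, mode="edge", anti_aliasing=False)


def _logit(graph, batch, class_index):
    return run_forward(graph, batch)[graph.logit_name][:, class_index]


def _as_batch(image):
    x = np.asarray(image, dtype=DTYPE)
    return x[None] if x.ndim == 3 else x


# ---------------------------------------------------------------------------
# Perturbation-based
# ---------------------------------------------------------------------------

def occlusion_map(graph, image, class_index, mask_size=32, stride=16,
                  mask_value=0.5, batch_size=64):
    """Slide a mask_size x mask_size patch of ``mask_value`` over the image;
    heat = score(unmodified) - score(masked), averaged over overlaps."""
    x = _as_batch(image)[0]
    h, w = x.shape[:2]
    if mask_size > min(h, w):
        raise ConfigurationError("mask larger than the image")
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    base = float(_logit(graph, x[None], class_index)[0])
    tops = list(range(0, h - mask_size + 1, stride))
    lefts = list(range(0, w - mask_size + 1, stride))
    positions = [(t, l) for t in tops for l in lefts]
    drops = np.zeros(len(positions))
    for i in range(0, len(positions), batch_size):
        chunk = positions[i:i + batch_size]
        batch = np.repeat(x[None], len(chunk), axis=0)
        for b, (t, l) in enumerate(chunk):
            batch[b, t:t + mask_size, l:l + mask_size, :] = mask_value
        drops[i:i + len(chunk)] = base - _logit(graph, batch, class_index)
    heat = np.zeros((h, w))
    count = np.zeros((h, w))
    for (t, l), d in zip(positions, drops):
        heat[t:t + mask_size, l:l + mask_size] += d
        count[t:t + mask_size, l:l + mask_size] += 1
    raw = np.divide(heat, count, out=np.zeros_like(heat), where=count > 0)
    return AttentionMap(_normalize(raw), raw, "occlusion", class_index)


def superpixel_surrogate_map(graph, image, class_index, n_segments=32,
                             n_samples=256, seed=0, replacement=0.5,
                             batch_size=64, segments=None):
    """LIME-style: segment into superpixels, perturb by switching segments
    off (to the replacement color), fit a least-squares linear surrogate
    from on/off patterns to class scores; heat = each pixel's segment weight.

    When the full on/off design (2^n_segments patterns) fits within
    ``n_samples`` it is enumerated exhaustively; otherwise patterns are
    sampled.  A singular design falls back to ridge damping (lambda=1e-3)
    with a warning.  A precomputed ``segments`` label image overrides the
    SLIC segmentation.
    """
    if n_segments < 2:
        raise ConfigurationError("need at least 2 superpixels")
    x = _as_batch(image)[0]
    if segments is None:
        segments = slic(np.ascontiguousarray(x), n_segments=n_segments,
                        start_label=0, channel_axis=-1)
    seg_ids = np.unique(segments)
    k = len(seg_ids)
    if n_samples < k:
        raise ConfigurationError("n_samples must be >= the number of superpixels")
    if 2 ** k <= n_samples:
        z = ((np.arange(2 ** k)[:, None] >> np.arange(k)) & 1).astype(float)
    else:
        rng = np.random.default_rng(seed)
        z = rng.integers(0, 2, size=(n_samples, k)).astype(float)
        z[0] = 1.0  # always include the unperturbed image
    masks = np.stack([(segments == s) for s in seg_ids], axis=-1)  # h, w, k
    scores = np.empty(len(z))
    for i in range(0, len(z), batch_size):
        zz = z[i:i + batch_size]
        on = np.einsum("hwk,bk->bhw", masks.astype(float), zz)[..., None]
        batch = x[None] * on + replacement * (1 - on)
        scores[i:i + len(zz)] = _logit(graph, batch, class_index)
    design = np.column_stack([z, np.ones(len(z))])
    gram = design.T @ design
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        warnings.warn("singular surrogate design; refitting with ridge damping")
        gram = gram + 1e-3 * np.eye(gram.shape[0])
        coef = np.linalg.solve(gram, design.T @ scores)
    else:
        coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    weights = coef[:k]
    raw = np.einsum("hwk,k->hw", masks.astype(float), weights)
    return AttentionMap(_normalize(raw), raw, "lime", class_index)


# ---------------------------------------------------------------------------
# Gradient-based
# ---------------------------------------------------------------------------

def vanilla_saliency(graph, image, class_index):
    """|d logit / d input|, max over color channels."""
    x = _as_batch(image)
    state = run_forward(graph, x)
    g = backward(graph, state, class_logit_target(graph, class_index))[graph.input_name][0]
    raw = _channel_max_abs(g)
    return AttentionMap(_normalize(raw), g, "vanilla", class_index)


def guided_backprop_map(graph, image, class_index):
    """Guided back-propagation: ReLU backward signals are zeroed where the
    forward pre-activation or the incoming backward signal is negative."""
    x = _as_batch(image)
    state = run_forward(graph, x)
    g = backward(graph, state, class_logit_target(graph, class_index),
                 rule=PropagationRule("guided"))[graph.input_name][0]
    raw = _channel_max_abs(g)
    return AttentionMap(_normalize(raw), g, "guided", class_index)


def integrated_gradients_map(graph, image, class_index, steps=50, baseline=None,
                             batch_size=16):
    """Path-integrated gradients from a baseline (default black) to the
    input, midpoint rule: attribution_i = (x_i - x0_i) * mean_alpha
    dF/dx_i(x0 + alpha (x - x0))."""
    if steps < 1:
        raise ConfigurationError("steps must be >= 1")
    x = _as_batch(image)[0]
    x0 = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=DTYPE)
    alphas = (np.arange(steps) + 0.5) / steps
    total = np.zeros_like(x)
    for i in range(0, steps, batch_size):
        aa = alphas[i:i + batch_size]
        batch = x0[None] + aa[:, None, None, None] * (x - x0)[None]
        state = run_forward(graph, batch)
        g = backward(graph, state, class_logit_target(graph, class_index))[graph.input_name]
        total += g.sum(axis=0)
    attr = (x - x0) * total / steps
    raw = _channel_max_abs(attr)
    return AttentionMap(_normalize(raw), attr, "integrated_gradients", class_index)


def grad_cam_map(graph, image, class_index, layer, relu_rule="vanilla"):
    """Grad-CAM at any spatial layer: channel weights are the spatial mean of
    d(logit)/d(activation); the map is ReLU of the weighted activation sum,
    bilinearly upsampled to the input resolution."""
    if len(graph.shapes[graph.spec(layer).name]) != 3:
        raise ConfigurationError(f"layer {layer!r} has no spatial extent")
    x = _as_batch(image)
    state = run_forward(graph, x)
    rule = PropagationRule("guided" if relu_rule == "guided" else "vanilla")
    sig = backward(graph, state, class_logit_target(graph, class_index), rule=rule)
    if layer not in sig:
        raise ConfigurationError(f"layer {layer!r} does not feed the class logit")
    g = sig[layer][0]
    a = state[layer][0]
    weights = g.mean(axis=(0, 1))
    cam = np.maximum((a * weights).sum(axis=-1), 0.0)
    raw = _upsample(cam, x.shape[1:3])
    return AttentionMap(_normalize(raw), raw, "grad_cam", class_index, layer)


# ---------------------------------------------------------------------------
# Reference-based
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """Healthy reference images plus cached per-layer activation thresholds.

    The "activation threshold" of a neuron is its mean activation over the
    reference batch.  ``threshold_mode`` decides what a neuron is: "neuron"
    (default) keeps one threshold per spatial position and channel — the
    reference leaves act as a positional control, so shared structure
    (background, leaf body) cancels; "channel" additionally averages over
    spatial positions, giving one scalar per channel.
    """

    images: np.ndarray
    threshold_mode: str = "neuron"
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = _as_batch(self.images)
        if len(self.images) == 0:
            raise ConfigurationError("empty reference batch")
        if self.threshold_mode not in ("neuron", "channel"):
            raise ConfigurationError(f"unknown threshold mode {self.threshold_mode!r}")

    def threshold(self, graph, layer):
        key = (layer, self.threshold_mode)
        if key not in self.thresholds:
            act = run_forward(graph, self.images)[layer]
            axes = (0,) if self.threshold_mode == "neuron" else tuple(range(act.ndim - 1))
            self.thresholds[key] = act.mean(axis=axes)
        return self.thresholds[key]


def deeplift_map(graph, image, class_index, reference):
    """DeepLIFT rescale-rule contributions against a single reference image;
    heat = channel-max |contribution|, raw signed contributions retained."""
    x = _as_batch(image)
    ref = _as_batch(reference.images[0] if isinstance(reference, ReferenceSet)
                    else reference)
    if ref.shape != x.shape:
        raise ConfigurationError("reference image shape differs from the input")
    state = run_forward(graph, x)
    ref_state = run_forward(graph, ref)
    mult = backward(graph, state, class_logit_target(graph, class_index),
                    rule=PropagationRule("rescale", ref_state))[graph.input_name]
    contrib = (mult * (x - ref))[0]
    raw = _channel_max_abs(contrib)
    return AttentionMap(_normalize(raw), contrib, "deeplift", class_index)


def explanation_map(graph, image, references, layer, top_k=3):
    """Forward-only reference-based map: rectify each channel against its
    reference threshold (n_k = max(0, a_k - t_k)), rank channels by the
    spatial sum of n_k and sum the top_k, upsampled to input size."""
    if len(graph.shapes[graph.spec(layer).name]) != 3:
        raise ConfigurationError(f"layer {layer!r} has no spatial extent")
    x = _as_batch(image)
    t = references.threshold(graph, layer)
    if top_k > t.shape[-1]:
        raise ConfigurationError("top_k exceeds the channel count")
    act = run_forward(graph, x)[layer][0]
    n = np.maximum(act - t, 0.0)
    order = np.argsort(-n.sum(axis=(0, 1)), kind="stable")
    cam = n[:, :, order[:top_k]].sum(axis=-1)
    raw = _upsample(cam, x.shape[1:3])
    return AttentionMap(_normalize(raw), raw, "explanation", None, layer)


# ---------------------------------------------------------------------------
# Layer scan
# ---------------------------------------------------------------------------

def layer_scan(graph, image, method, layers, class_index=None, references=None,
               mask=None, **kwargs):
    """Run a layer-targetable method over several layers.

    Returns (list of AttentionMap, DataFrame with one row per layer; when a
    lesion ``mask`` is supplied the table includes the heat fraction on the
    mask).
    """
    maps, rows = [], []
    for layer in layers:
        if method == "grad_cam":
            m = grad_cam_map(graph, image, class_index, layer, **kwargs)
        elif method == "explanation":
            m = explanation_map(graph, image, references, layer, **kwargs)
        else:
            raise ConfigurationError(f"layer_scan supports grad_cam/explanation, not {method!r}")
        maps.append(m)
        row = {"layer": layer, "native_h": graph.shapes[layer][0],
               "native_w": graph.shapes[layer][1]}
        if mask is not None:
            total = m.values.sum()
            row["lesion_heat_fraction"] = (
                float(m.values[mask.astype(bool)].sum() / total) if total > 0 else 0.0)
        rows.append(row)
    return maps, pd.DataFrame(rows)


def overlay(image, amap, cmap="jet", alpha=0.5):
    """Jet-colormap overlay of a map on its image (for PNG export)."""
    import matplotlib

    rgba = matplotlib.colormaps[cmap](amap.values)[:, :, :3]
    return np.clip((1 - alpha) * np.asarray(image) + alpha * rgba, 0, 1)
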