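"""Visualization I: hidden-layer output capture, channel grids, entropy.

The most direct view of what a CNN computes: halt the forward pass at a
layer of interest and render its post-activation channels as a grid of
independently normalized grayscale tiles.  Shannon entropy of a rendered
image (in bits over 8-bit gray levels) serves as the complexity score used
to compare feature-visualization renders across depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray

from .netcore import forward


@dataclass
class ChannelStack:
    """Post-activation output of one layer for one image: (h, w, c)."""

    layer: str
    activations: np.ndarray
    source: str = ""


def extract_intermediate(graph, image, layer):
    """Forward ``image`` and capture ``layer``'s post-activation output."""
    _, captured = forward(graph, image, capture=(layer,))
    act = captured[layer][0]
    if act.ndim == 1:  # flat layers render as 1 x c "maps"
        act = act[None, None, :]
    return ChannelStack(layer, act)


def render_grid(stack, max_channels=64, separator=1):
    """Tile up to ``max_channels`` channels into a near-square grayscale grid.

    Each channel is min-max normalized independently (constant channels map
    to zero); tiles are laid out row-major with 1-px separators.
    """
    if max_channels < 1:
        raise ValueError("max_channels must be >= 1")
    act = stack.activations
    h, w, c = act.shape
    c = min(c, max_channels)
    cols = int(np.ceil(np.sqrt(c)))
    rows = int(np.ceil(c / cols))
    grid = np.zeros((rows * h + (rows - 1) * separator,
                     cols * w + (cols - 1) * separator))
    for k in range(c):
        ch = act[:, :, k]
        lo, hi = ch.min(), ch.max()
        tile = np.zeros_like(ch) if hi <= lo else (ch - lo) / (hi - lo)
        r, q = divmod(k, cols)
        grid[r * (h + separator):r * (h + separator) + h,
             q * (w + separator):q * (w + separator) + w] = tile
    return grid


def shannon_entropy(image):
    """Shannon entropy (bits) of an image over 8-bit gray levels.

    RGB input is converted to grayscale with ITU-R 709 luminance weights
    (0.2125, 0.7154, 0.0721), quantized to 8 bits; H = -sum p log2 p, so
    0 <= H <= 8.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = rgb2gray(img)
    levels = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())
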