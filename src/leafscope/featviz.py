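"""Visualization II: feature visualization by activation maximization.

Synthesizes the image that maximally drives a chosen neuron (channel) by
gradient ascent.  The image is parameterized in a color-decorrelated Fourier
space: complex half-plane spectra per color component, scaled at
initialization so energy falls off as 1/frequency, rendered by inverse FFT,
mixed through a 3x3 color decorrelation matrix and squashed to [0, 1] with a
sigmoid.  Optimization uses Adam on the mean activation of the neuron of
interest, with no explicit regularization terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .netcore import (DTYPE, PropagationRule, backward, neuron_mean_target,
                      run_forward, ConfigurationError)

# Cholesky-style factor of an empirical natural-image RGB covariance,
# normalized by its largest column norm (the conventional triple used for
# color decorrelation in activation-maximization work).
_COLOR_CORRELATION = np.array([[0.26, 0.09, 0.02],
                               [0.27, 0.00, -0.05],
                               [0.27, -0.09, 0.03]])
DEFAULT_DECORRELATION = _COLOR_CORRELATION / np.linalg.norm(_COLOR_CORRELATION, axis=0).max()


def decorrelation_from_images(images):
    """Estimate the 3x3 decorrelation matrix (Cholesky factor of the RGB
    covariance, scaled like the default) from a stack of images."""
    px = np.concatenate([np.asarray(im).reshape(-1, 3) for im in images])
    cov = np.cov(px.T)
    chol = np.linalg.cholesky(cov + 1e-8 * np.eye(3))
    return chol / np.linalg.norm(chol, axis=0).max()


@dataclass
class SpectralImage:
    """Half-plane complex spectra (3, H, W//2+1) plus render parameters."""

    spectrum: np.ndarray
    size: int
    decorrelation: np.ndarray = field(default_factory=lambda: DEFAULT_DECORRELATION.copy())
    seed: int = 0


@dataclass(frozen=True)
class NeuronSelector:
    """A unit to maximize: layer name + channel; activation is averaged over
    spatial positions (flat layers use the unit directly)."""

    layer: str
    channel: int


def frequency_scale(size):
    """Per-coefficient render scale: 1/frequency (capped at the image scale)
    times sqrt(H*W), so spectral energy falls off as 1/f and the gradient is
    preconditioned accordingly."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    fd = np.sqrt(fy * fy + fx * fx)
    return size / np.maximum(fd, 1.0 / size)


def init_spectral(size, seed=0, noise_sd=0.1, decorrelation=None):
    """Gaussian spectral coefficients, seed-deterministic.

    Coefficients multiply the 1/f :func:`frequency_scale` at render time, so
    a white-noise draw here renders as 1/f-energy pink noise.  The draw is
    projected onto the subspace of spectra that are exact rfft2 transforms
    of real fields, so render/transform round-trips are exact.
    """
    if size < 8:
        raise ConfigurationError("spectral image size must be >= 8")
    rng = np.random.default_rng(seed)
    shape = (3, size, size // 2 + 1)
    spec = (rng.normal(size=shape) + 1j * rng.normal(size=shape)) * noise_sd
    spec = np.fft.rfft2(np.fft.irfft2(spec, s=(size, size)))  # hermitian projection
    dec = DEFAULT_DECORRELATION.copy() if decorrelation is None else np.asarray(decorrelation)
    return SpectralImage(spec, size, dec, seed)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def render_pixel(spectral, return_pre=False):
    """Spectrum -> image: 1/f scaling, inverse FFT per component, color
    decorrelation across the channel axis, sigmoid squash to [0, 1]."""
    s = spectral.size
    scaled = spectral.spectrum * frequency_scale(s)
    pre = np.stack([np.fft.irfft2(scaled[c], s=(s, s)) for c in range(3)], axis=-1)
    mixed = pre @ spectral.decorrelation.T
    img = _sigmoid(mixed)
    return (img, pre, mixed) if return_pre else img


def _irfft2_adjoint(g, size):
    """Adjoint of ``np.fft.irfft2(s, s=(size, size))`` as a real-linear map,
    in the dL/dRe + i dL/dIm gradient convention."""
    w = size
    wts = np.full(w // 2 + 1, 2.0 / w)
    wts[0] = 1.0 / w
    if w % 2 == 0:
        wts[-1] = 1.0 / w
    G = np.fft.rfft(g, axis=1) * wts
    G[:, 0] = G[:, 0].real
    if w % 2 == 0:
        G[:, -1] = G[:, -1].real
    return np.fft.fft(G, axis=0) / size


def spectral_gradient(spectral, pixel_grad, mixed):
    """Chain a d(objective)/d(pixels) array back to the spectrum."""
    gm = pixel_grad * _sigmoid(mixed) * (1.0 - _sigmoid(mixed))
    gpre = gm @ spectral.decorrelation
    adj = np.stack([_irfft2_adjoint(gpre[:, :, c], spectral.size) for c in range(3)])
    return adj * frequency_scale(spectral.size)


def resolve_selector(graph, selector, pre_relu=False):
    """Map a selector onto the layer actually optimized.

    A GAP neuron is the spatial mean of its parent channel, so GAP selectors
    retarget the parent feature layer (same objective, cheaper backward).
    ``pre_relu`` steps past a ReLU to its pre-activation — the conventional
    activation-maximization target, which keeps units optimizable even when
    they are inactive on the initial noise image.
    """
    layer = selector.layer
    spec = graph.spec(layer)
    if spec.kind == "global_avg_pool":
        layer = spec.parents[0]
        spec = graph.spec(layer)
    if pre_relu and spec.kind == "relu":
        layer = spec.parents[0]
    if selector.channel >= graph.shapes[layer][-1]:
        raise ConfigurationError(
            f"channel {selector.channel} out of range for layer {layer!r}")
    return NeuronSelector(layer, selector.channel)


def visualize_neuron(graph, selector, steps=512, lr=0.05, seed=0, noise_sd=0.1,
                     decorrelation=None, rule=None, pre_relu=False):
    """Gradient-ascend the mean activation of a neuron over the spectral
    parameterization; returns (final render, per-step activation trace)."""
    selector = resolve_selector(graph, selector, pre_relu=pre_relu)
    size = graph.input_shape()[0]
    sp = init_spectral(size, seed=seed, noise_sd=noise_sd, decorrelation=decorrelation)
    rule = rule or PropagationRule()
    target = neuron_mean_target(selector.layer, selector.channel)
    b1, b2, eps = 0.9, 0.999, 1e-7
    m = np.zeros_like(sp.spectrum)
    v = np.zeros(sp.spectrum.shape)
    trace = []
    init_render = None
    for t in range(1, steps + 1):
        img, pre, mixed = render_pixel(sp, return_pre=True)
        if init_render is None:
            init_render = img.copy()
        state = run_forward(graph, img[None])
        act = state[selector.layer][0]
        obj = float(act[..., selector.channel].mean()) if act.ndim == 3 \
            else float(act[selector.channel])
        trace.append(obj)
        sig = backward(graph, state, target, rule=rule)
        gpix = sig[graph.input_name][0]
        gs = spectral_gradient(sp, gpix, mixed)
        gnorm = np.sqrt((gs.real ** 2 + gs.imag ** 2).sum())
        if t == 1 and gnorm == 0.0:
            warnings.warn(f"zero gradient for {selector}; returning initial render")
            return init_render, np.asarray(trace)
        # Adam ascent on (Re, Im) jointly
        m = b1 * m + (1 - b1) * gs
        v = b2 * v + (1 - b2) * (gs.real ** 2 + gs.imag ** 2)
        mhat = m / (1 - b1 ** t)
        vhat = v / (1 - b2 ** t)
        sp.spectrum = sp.spectrum + lr * mhat / (np.sqrt(vhat) + eps)
    return render_pixel(sp), np.asarray(trace)
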