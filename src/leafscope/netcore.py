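"""Minimal layer-graph neural-network engine.

A :class:`LayerGraph` is a DAG of typed layers (conv2d, batchnorm, relu,
pooling, dense, concat, softmax) with explicitly stored weight arrays.
It supports

* forward evaluation with capture of intermediate activations,
* backward propagation under pluggable unit rules (``vanilla`` gradients,
  ``guided`` back-propagation, and the DeepLIFT ``rescale`` rule against a
  reference forward state),
* exact parameter accounting,
* an InceptionV3-like feature-extractor builder and truncation surgery
  ("layer shaving"), and
* a small Adam training loop with lowest-validation-loss model selection.

Conventions: channels-last (N, H, W, C) float64 arrays, row-major, origin
top-left; all spatial sizes are reported H x W.  Batchnorm runs in inference
mode (moving statistics) everywhere except inside :func:`train`.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64

LAYER_KINDS = {
    "input", "conv2d", "batchnorm", "relu", "maxpool", "avgpool",
    "global_avg_pool", "dense", "concat", "softmax",
}


class ConfigurationError(ValueError):
    """Raised when a layer graph or a request against it is ill-formed."""


# ---------------------------------------------------------------------------
# Layer specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One typed node of the layer graph.

    ``hyper`` is kind-specific: kernel/pool size ``(kh, kw)``, ``stride``,
    ``padding`` in {"same", "valid"}, ``channels``/``units``, ``bias``,
    ``scale`` (batchnorm learnable scale), ``shape`` (input only).
    """

    name: str
    kind: str
    hyper: dict = field(default_factory=dict)
    parents: tuple = ()


def input_layer(name, shape):
    return LayerSpec(name, "input", {"shape": tuple(shape)})


def conv2d(name, parent, channels, kernel, stride=1, padding="same", bias=False):
    kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
    return LayerSpec(name, "conv2d",
                     {"channels": int(channels), "kernel": (int(kh), int(kw)),
                      "stride": int(stride), "padding": padding, "bias": bool(bias)},
                     (parent,))


def batchnorm(name, parent, scale=True, eps=1e-3):
    return LayerSpec(name, "batchnorm", {"scale": bool(scale), "eps": float(eps)}, (parent,))


def relu(name, parent):
    return LayerSpec(name, "relu", {}, (parent,))


def maxpool(name, parent, pool, stride=None, padding="valid"):
    kh, kw = (pool, pool) if np.isscalar(pool) else pool
    stride = stride if stride is not None else kh
    return LayerSpec(name, "maxpool",
                     {"pool": (int(kh), int(kw)), "stride": int(stride), "padding": padding},
                     (parent,))


def avgpool(name, parent, pool, stride=None, padding="valid"):
    kh, kw = (pool, pool) if np.isscalar(pool) else pool
    stride = stride if stride is not None else kh
    return LayerSpec(name, "avgpool",
                     {"pool": (int(kh), int(kw)), "stride": int(stride), "padding": padding},
                     (parent,))


def global_avg_pool(name, parent):
    return LayerSpec(name, "global_avg_pool", {}, (parent,))


def dense(name, parent, units, bias=True):
    return LayerSpec(name, "dense", {"units": int(units), "bias": bool(bias)}, (parent,))


def concat(name, parents):
    return LayerSpec(name, "concat", {}, tuple(parents))


def softmax(name, parent):
    return LayerSpec(name, "softmax", {}, (parent,))


# ---------------------------------------------------------------------------
# Shape inference
# ---------------------------------------------------------------------------

def _pool_out(size, k, stride, padding):
    if padding == "same":
        return -(-size // stride)
    return (size - k) // stride + 1


def _pad_amounts(size, k, stride, padding):
    """(before, after) zero-padding along one spatial axis."""
    if padding == "same":
        out = -(-size // stride)
        total = max((out - 1) * stride + k - size, 0)
        return total // 2, total - total // 2
    return 0, 0


def infer_shapes(specs):
    """Map layer name -> output shape, (H, W, C) spatial or (C,) flat.

    Validates kinds, parent references, acyclicity (specs must already be
    topologically ordered: parents precede children) and concat spatial
    agreement.
    """
    shapes = {}
    for s in specs:
        if s.kind not in LAYER_KINDS:
            raise ConfigurationError(f"unknown layer kind {s.kind!r} at {s.name!r}")
        for p in s.parents:
            if p not in shapes:
                raise ConfigurationError(
                    f"layer {s.name!r}: parent {p!r} undefined (or graph not topologically ordered)")
        if s.kind == "input":
            shapes[s.name] = tuple(s.hyper["shape"])
            continue
        psh = [shapes[p] for p in s.parents]
        if s.kind == "conv2d":
            h, w, c = psh[0]
            kh, kw = s.hyper["kernel"]
            st, pad = s.hyper["stride"], s.hyper["padding"]
            shapes[s.name] = (_pool_out(h, kh, st, pad), _pool_out(w, kw, st, pad),
                              s.hyper["channels"])
        elif s.kind in ("maxpool", "avgpool"):
            h, w, c = psh[0]
            kh, kw = s.hyper["pool"]
            st, pad = s.hyper["stride"], s.hyper["padding"]
            shapes[s.name] = (_pool_out(h, kh, st, pad), _pool_out(w, kw, st, pad), c)
        elif s.kind in ("batchnorm", "relu"):
            shapes[s.name] = psh[0]
        elif s.kind == "global_avg_pool":
            if len(psh[0]) != 3:
                raise ConfigurationError(f"{s.name!r}: global_avg_pool needs a spatial parent")
            shapes[s.name] = (psh[0][2],)
        elif s.kind == "dense":
            if len(psh[0]) != 1:
                raise ConfigurationError(f"{s.name!r}: dense needs a flat parent")
            shapes[s.name] = (s.hyper["units"],)
        elif s.kind == "concat":
            hw = {sh[:2] for sh in psh}
            if len(hw) != 1 or len(psh[0]) != 3:
                raise ConfigurationError(
                    f"{s.name!r}: concat parents must share spatial dimensions")
            shapes[s.name] = psh[0][:2] + (sum(sh[2] for sh in psh),)
        elif s.kind == "softmax":
            shapes[s.name] = psh[0]
    return shapes


# ---------------------------------------------------------------------------
# Graph container
# ---------------------------------------------------------------------------

@dataclass
class LayerGraph:
    """Ordered layer specs plus their weight arrays.

    ``weights[layer][param]`` holds the arrays: conv ``kernel`` (kh, kw,
    cin, cout) and optional ``bias``; batchnorm ``gamma`` (if scale),
    ``beta``, ``moving_mean``, ``moving_var``; dense ``W`` (in, units) and
    ``b``.  ``counters`` instruments forward/backward traffic (used by the
    attention-map cost contracts).
    """

    specs: list
    weights: dict
    shapes: dict = field(default_factory=dict)
    counters: dict = field(default_factory=lambda: {"forward_images": 0, "backward_calls": 0})

    def __post_init__(self):
        if not self.shapes:
            self.shapes = infer_shapes(self.specs)
        self._by_name = {s.name: s for s in self.specs}

    def spec(self, name):
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"unknown layer {name!r}") from None

    def layer_names(self):
        return [s.name for s in self.specs]

    @property
    def input_name(self):
        return next(s.name for s in self.specs if s.kind == "input")

    @property
    def output_name(self):
        return self.specs[-1].name

    @property
    def logit_name(self):
        """The pre-softmax layer (or the final layer when no softmax exists)."""
        last = self.specs[-1]
        return last.parents[0] if last.kind == "softmax" else last.name

    def input_shape(self):
        return self.shapes[self.input_name]

    def copy(self):
        return LayerGraph(list(self.specs), copy.deepcopy(self.weights), dict(self.shapes))

    def gap_head(self):
        """(gap_name, dense_name, W, b) of a GAP -> dense classifier head."""
        d = self.spec(self.logit_name)
        if d.kind != "dense":
            raise ConfigurationError("graph has no dense head")
        gap = d.parents[0]
        if self.spec(gap).kind != "global_avg_pool":
            raise ConfigurationError("dense head is not fed by a global_avg_pool layer")
        w = self.weights[d.name]
        return gap, d.name, w["W"], w.get("b", np.zeros(w["W"].shape[1], dtype=DTYPE))

    def reset_counters(self):
        self.counters["forward_images"] = 0
        self.counters["backward_calls"] = 0


def _alloc_weights(spec, shapes, rng):
    """Weight arrays for one layer; He-normal kernels when rng is given."""
    out = {}
    if spec.kind == "conv2d":
        cin = shapes[spec.parents[0]][2]
        kh, kw = spec.hyper["kernel"]
        cout = spec.hyper["channels"]
        shape = (kh, kw, cin, cout)
        if rng is None:
            out["kernel"] = np.zeros(shape, dtype=DTYPE)
        else:
            out["kernel"] = rng.normal(0.0, np.sqrt(2.0 / (kh * kw * cin)), shape).astype(DTYPE)
        if spec.hyper.get("bias", False):
            out["bias"] = np.zeros(cout, dtype=DTYPE)
    elif spec.kind == "batchnorm":
        c = shapes[spec.parents[0]][-1]
        if spec.hyper.get("scale", True):
            out["gamma"] = np.ones(c, dtype=DTYPE)
        out["beta"] = np.zeros(c, dtype=DTYPE)
        out["moving_mean"] = np.zeros(c, dtype=DTYPE)
        out["moving_var"] = np.ones(c, dtype=DTYPE)
    elif spec.kind == "dense":
        cin = shapes[spec.parents[0]][0]
        units = spec.hyper["units"]
        if rng is None:
            out["W"] = np.zeros((cin, units), dtype=DTYPE)
        else:
            out["W"] = rng.normal(0.0, np.sqrt(2.0 / cin), (cin, units)).astype(DTYPE)
        if spec.hyper.get("bias", True):
            out["b"] = np.zeros(units, dtype=DTYPE)
    return out


def build_graph(specs, init="zeros", seed=0, weights=None):
    """Validate specs, allocate weights and return a :class:`LayerGraph`.

    ``init``: "zeros", "random" (seed-deterministic He-normal kernels) or
    "provided" with a ``weights`` dict.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ConfigurationError(f"duplicate layer name {dup!r}")
    n_inputs = sum(1 for s in specs if s.kind == "input")
    if n_inputs != 1:
        raise ConfigurationError(f"graph must have exactly one input layer, found {n_inputs}")
    shapes = infer_shapes(specs)
    for s in specs:
        if s.kind == "conv2d" and s.hyper.get("bias", False):
            children = [c for c in specs if s.name in c.parents]
            if any(c.kind == "batchnorm" for c in children):
                raise ConfigurationError(
                    f"conv layer {s.name!r} carries a bias but feeds a batchnorm layer")
    if init == "provided":
        if weights is None:
            raise ConfigurationError("init='provided' requires a weights dict")
        w = copy.deepcopy(weights)
    else:
        rng = np.random.default_rng(seed) if init == "random" else None
        w = {s.name: _alloc_weights(s, shapes, rng) for s in specs}
        w = {k: v for k, v in w.items() if v}
    return LayerGraph(list(specs), w, shapes)


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pads, pad_val=0.0):
    (ph0, ph1), (pw0, pw1) = pads
    xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)), constant_values=pad_val)
    v = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N, H', W', C, kh, kw
    v = v[:, ::stride, ::stride]
    return np.moveaxis(v, 3, 5)  # N, OH, OW, kh, kw, C


def _col2im(gcols, x_shape, kh, kw, stride, pads):
    n, h, w, c = x_shape
    (ph0, ph1), (pw0, pw1) = pads
    oh, ow = gcols.shape[1:3]
    gx = np.zeros((n, h + ph0 + ph1, w + pw0 + pw1, c), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            gx[:, i:i + oh * stride:stride, j:j + ow * stride:stride] += gcols[:, :, :, i, j, :]
    return gx[:, ph0:ph0 + h, pw0:pw0 + w]


def _spatial_pads(spec, in_shape):
    kh, kw = spec.hyper["kernel"] if spec.kind == "conv2d" else spec.hyper["pool"]
    st, pad = spec.hyper["stride"], spec.hyper["padding"]
    return (kh, kw, st,
            (_pad_amounts(in_shape[0], kh, st, pad), _pad_amounts(in_shape[1], kw, st, pad)))


# ---------------------------------------------------------------------------
# Forward
# ---------------------------------------------------------------------------

@dataclass
class ForwardState:
    """Activations of every layer for one batch (inputs included)."""

    graph: LayerGraph
    outputs: dict
    training: bool = False

    def __getitem__(self, name):
        return self.outputs[name]


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def run_forward(graph, batch, training=False, update_stats=None, bn_momentum=0.9):
    """Evaluate every layer; returns a :class:`ForwardState`.

    ``training=True`` switches batchnorm to batch statistics and (for layers
    listed in ``update_stats``, default all) updates the moving statistics
    in place.
    """
    x = np.asarray(batch, dtype=DTYPE)
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != tuple(graph.input_shape()):
        raise ConfigurationError(
            f"input batch shape {x.shape[1:]} does not match graph input "
            f"{tuple(graph.input_shape())}")
    graph.counters["forward_images"] += x.shape[0]
    outs = {}
    for s in graph.specs:
        if s.kind == "input":
            outs[s.name] = x
            continue
        p = [outs[q] for q in s.parents]
        if s.kind == "conv2d":
            kh, kw, st, pads = _spatial_pads(s, p[0].shape[1:])
            cols = _im2col(p[0], kh, kw, st, pads)
            n, oh, ow = cols.shape[:3]
            k = graph.weights[s.name]["kernel"]
            y = cols.reshape(n * oh * ow, -1) @ k.reshape(-1, k.shape[-1])
            y = y.reshape(n, oh, ow, -1)
            if "bias" in graph.weights[s.name]:
                y = y + graph.weights[s.name]["bias"]
            outs[s.name] = y
        elif s.kind == "maxpool":
            kh, kw, st, pads = _spatial_pads(s, p[0].shape[1:])
            win = _im2col(p[0], kh, kw, st, pads, pad_val=-np.inf)
            outs[s.name] = win.max(axis=(3, 4))
        elif s.kind == "avgpool":
            kh, kw, st, pads = _spatial_pads(s, p[0].shape[1:])
            win = _im2col(p[0], kh, kw, st, pads)
            cnt = _im2col(np.ones_like(p[0]), kh, kw, st, pads)
            outs[s.name] = win.sum(axis=(3, 4)) / cnt.sum(axis=(3, 4))
        elif s.kind == "batchnorm":
            w = graph.weights[s.name]
            gamma = w.get("gamma", 1.0)
            axes = tuple(range(p[0].ndim - 1))
            if training:
                mu = p[0].mean(axis=axes)
                var = p[0].var(axis=axes)
                if update_stats is None or s.name in update_stats:
                    w["moving_mean"] *= bn_momentum
                    w["moving_mean"] += (1 - bn_momentum) * mu
                    w["moving_var"] *= bn_momentum
                    w["moving_var"] += (1 - bn_momentum) * var
            else:
                mu, var = w["moving_mean"], w["moving_var"]
            outs[s.name] = gamma * (p[0] - mu) / np.sqrt(var + s.hyper["eps"]) + w["beta"]
        elif s.kind == "relu":
            outs[s.name] = np.maximum(p[0], 0.0)
        elif s.kind == "global_avg_pool":
            outs[s.name] = p[0].mean(axis=(1, 2))
        elif s.kind == "dense":
            w = graph.weights[s.name]
            outs[s.name] = p[0] @ w["W"] + w.get("b", 0.0)
        elif s.kind == "concat":
            outs[s.name] = np.concatenate(p, axis=-1)
        elif s.kind == "softmax":
            outs[s.name] = _softmax(p[0])
    return ForwardState(graph, outs, training)


def forward(graph, batch, capture=()):
    """Inference-mode forward; returns (final output, {captured layer: activation}).

    Softmax outputs sum to 1 per image; captured maps are the named layers'
    post-activation outputs.
    """
    for name in capture:
        graph.spec(name)
    state = run_forward(graph, batch, training=False)
    return state[graph.output_name], {name: state[name] for name in capture}


# ---------------------------------------------------------------------------
# Backward with pluggable rules
# ---------------------------------------------------------------------------

@dataclass
class PropagationRule:
    """Backward unit rule: 'vanilla', 'guided' or 'rescale'.

    ``rescale`` back-propagates DeepLIFT-style multipliers using activation
    differences against ``reference`` (a ForwardState of the reference
    input), with the exact linear rule at affine layers and a gradient
    fallback where the input difference is below ``rescale_eps``.
    """

    rule: str = "vanilla"
    reference: ForwardState | None = None
    rescale_eps: float = 1e-7

    def __post_init__(self):
        if self.rule not in ("vanilla", "guided", "rescale"):
            raise ConfigurationError(f"unknown propagation rule {self.rule!r}")
        if self.rule == "rescale" and self.reference is None:
            raise ConfigurationError("rescale rule requires reference activations")


def class_logit_target(graph, class_index):
    """Seed selector for d(pre-softmax logit of class)/d(...)."""
    return ("logit", int(class_index))


def neuron_mean_target(layer, channel):
    """Seed selector for the spatial-mean activation of one channel."""
    return ("neuron_mean", layer, int(channel))


def weighted_map_target(layer, weights):
    """Seed selector for a weighted sum over a captured layer's activations."""
    return ("weighted", layer, np.asarray(weights, dtype=DTYPE))


def _target_seed(graph, state, target):
    kind = target[0]
    if kind == "logit":
        name = graph.logit_name
        out = state[name]
        seed = np.zeros_like(out)
        seed[:, target[1]] = 1.0
        return name, seed
    if kind == "neuron_mean":
        name, ch = target[1], target[2]
        out = state[name]
        seed = np.zeros_like(out)
        if out.ndim == 4:
            seed[..., ch] = 1.0 / (out.shape[1] * out.shape[2])
        else:
            seed[:, ch] = 1.0
        return name, seed
    if kind == "weighted":
        name, w = target[1], target[2]
        out = state[name]
        return name, np.broadcast_to(w, out.shape).astype(DTYPE).copy()
    raise ConfigurationError(f"unknown backward target {target!r}")


def backward(graph, state, target, rule=None, param_grads=False):
    """Propagate a scalar objective's sensitivities back to the input.

    Returns a dict with per-layer backward signals (key = layer name,
    including the input layer) and, when ``param_grads`` is set, a
    ``"params"`` entry of per-layer weight gradients.  Under ``vanilla``
    the signals are exact gradients; under ``guided``/``rescale`` they are
    the corresponding modified signals (multipliers for rescale).
    """
    rule = rule or PropagationRule()
    graph.counters["backward_calls"] += 1
    tname, seed = _target_seed(graph, state, target)
    order = graph.layer_names()
    start = order.index(tname)
    sig = {tname: seed}
    pgrads = {}
    ref = rule.reference
    for s in reversed(graph.specs[:start + 1]):
        if s.name not in sig or s.kind == "input":
            continue
        g = sig[s.name]
        parents = s.parents
        pouts = [state[p] for p in parents]

        def send(pname, garr):
            if pname in sig:
                sig[pname] = sig[pname] + garr
            else:
                sig[pname] = garr

        if s.kind == "conv2d":
            kh, kw, st, pads = _spatial_pads(s, pouts[0].shape[1:])
            k = graph.weights[s.name]["kernel"]
            n, oh, ow, cout = g.shape
            gflat = g.reshape(n * oh * ow, cout)
            gcols = (gflat @ k.reshape(-1, cout).T).reshape(n, oh, ow, kh, kw, -1)
            send(parents[0], _col2im(gcols, pouts[0].shape, kh, kw, st, pads))
            if param_grads:
                cols = _im2col(pouts[0], kh, kw, st, pads).reshape(n * oh * ow, -1)
                pg = {"kernel": (cols.T @ gflat).reshape(k.shape)}
                if "bias" in graph.weights[s.name]:
                    pg["bias"] = gflat.sum(axis=0)
                pgrads[s.name] = pg
        elif s.kind == "maxpool":
            kh, kw, st, pads = _spatial_pads(s, pouts[0].shape[1:])
            win = _im2col(pouts[0], kh, kw, st, pads, pad_val=-np.inf)
            n, oh, ow = win.shape[:3]
            flat = win.reshape(n, oh, ow, kh * kw, -1)
            am = flat.argmax(axis=3)
            gcols = np.zeros_like(flat)
            np.put_along_axis(gcols, am[:, :, :, None, :], g[:, :, :, None, :], axis=3)
            send(parents[0], _col2im(gcols.reshape(win.shape), pouts[0].shape, kh, kw, st, pads))
        elif s.kind == "avgpool":
            kh, kw, st, pads = _spatial_pads(s, pouts[0].shape[1:])
            cnt = _im2col(np.ones_like(pouts[0]), kh, kw, st, pads).sum(axis=(3, 4))
            gc = (g / cnt)[:, :, :, None, None, :]
            gcols = np.broadcast_to(gc, g.shape[:3] + (kh, kw, g.shape[-1]))
            send(parents[0], _col2im(gcols, pouts[0].shape, kh, kw, st, pads))
        elif s.kind == "batchnorm":
            w = graph.weights[s.name]
            gamma = w.get("gamma", 1.0)
            eps = s.hyper["eps"]
            if state.training:
                x = pouts[0]
                axes = tuple(range(x.ndim - 1))
                m = np.prod([x.shape[a] for a in axes])
                mu = x.mean(axis=axes)
                var = x.var(axis=axes)
                xhat = (x - mu) / np.sqrt(var + eps)
                if param_grads:
                    pg = {"beta": g.sum(axis=axes)}
                    if "gamma" in w:
                        pg["gamma"] = (g * xhat).sum(axis=axes)
                    pgrads[s.name] = pg
                gx = (gamma / np.sqrt(var + eps)) * (
                    g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes))
                send(parents[0], gx)
            else:
                if param_grads:
                    axes = tuple(range(g.ndim - 1))
                    xhat = (pouts[0] - w["moving_mean"]) / np.sqrt(w["moving_var"] + eps)
                    pg = {"beta": g.sum(axis=axes)}
                    if "gamma" in w:
                        pg["gamma"] = (g * xhat).sum(axis=axes)
                    pgrads[s.name] = pg
                send(parents[0], g * gamma / np.sqrt(w["moving_var"] + eps))
        elif s.kind == "relu":
            pre = pouts[0]
            if rule.rule == "vanilla":
                send(parents[0], g * (pre > 0))
            elif rule.rule == "guided":
                send(parents[0], g * (pre > 0) * (g > 0))
            else:  # rescale: multiplier = delta_out / delta_in, gradient fallback
                dpre = pre - ref[parents[0]]
                dout = state[s.name] - ref[s.name]
                small = np.abs(dpre) < rule.rescale_eps
                with np.errstate(divide="ignore", invalid="ignore"):
                    mult = np.where(small, (pre > 0).astype(DTYPE), dout / np.where(small, 1.0, dpre))
                send(parents[0], g * mult)
        elif s.kind == "global_avg_pool":
            h, w_, _ = state[parents[0]].shape[1:]
            send(parents[0], np.broadcast_to(g[:, None, None, :] / (h * w_),
                                             state[parents[0]].shape).copy())
        elif s.kind == "dense":
            w = graph.weights[s.name]
            send(parents[0], g @ w["W"].T)
            if param_grads:
                pg = {"W": pouts[0].T @ g}
                if "b" in w:
                    pg["b"] = g.sum(axis=0)
                pgrads[s.name] = pg
        elif s.kind == "concat":
            off = 0
            for p in parents:
                c = state[p].shape[-1]
                send(p, g[..., off:off + c])
                off += c
        elif s.kind == "softmax":
            y = state[s.name]
            send(parents[0], y * (g - (g * y).sum(axis=-1, keepdims=True)))
    if param_grads:
        sig["params"] = pgrads
    return sig


def input_gradient(graph, batch, target, rule=None, state=None):
    """Convenience: backward signal at the input layer for one objective."""
    state = state if state is not None else run_forward(graph, batch)
    sig = backward(graph, state, target, rule=rule)
    return sig[graph.input_name], state


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

_NON_TRAINABLE = {("batchnorm", "moving_mean"), ("batchnorm", "moving_var")}


@dataclass
class ParamReport:
    """Per-layer and total parameter counts; moving statistics are reported
    as non-trainable but included in the totals."""

    rows: list  # (layer, trainable, non_trainable)

    @property
    def total(self):
        return sum(t + n for _, t, n in self.rows)

    @property
    def total_trainable(self):
        return sum(t for _, t, _ in self.rows)

    def per_layer(self):
        return {name: t + n for name, t, n in self.rows}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["layer", "trainable", "non_trainable"])


def count_parameters(graph):
    rows = []
    for s in graph.specs:
        w = graph.weights.get(s.name)
        if not w:
            continue
        t = sum(int(a.size) for p, a in w.items() if (s.kind, p) not in _NON_TRAINABLE)
        n = sum(int(a.size) for p, a in w.items() if (s.kind, p) in _NON_TRAINABLE)
        rows.append((s.name, t, n))
    return ParamReport(rows)


# ---------------------------------------------------------------------------
# InceptionV3-like builder
# ---------------------------------------------------------------------------

def _conv_block(specs, name, parent, channels, kernel, stride=1, padding="same"):
    specs.append(conv2d(f"{name}/conv", parent, channels, kernel, stride, padding, bias=False))
    specs.append(batchnorm(f"{name}/bn", f"{name}/conv", scale=False))
    specs.append(relu(name, f"{name}/bn"))
    return name


def build_inception_v3_like(n_classes, input_size=224, padding_dialect="all_same"):
    """InceptionV3-like feature extractor + GAP + dense classifier head.

    Stem Conv1..Conv5, inception modules Mixed0..Mixed10 (final feature
    depth 2048, Mixed5 depth 768), scale-free batchnorm after every
    convolution.  ``all_same`` pads every layer 'same' so a 224 input
    reaches Mixed10 at 7x7; ``standard_stem`` uses the conventional
    valid-padded stem and reduction blocks.  The parameter count is
    identical under both dialects.
    """
    if padding_dialect not in ("all_same", "standard_stem"):
        raise ConfigurationError(f"unknown padding dialect {padding_dialect!r}")
    if padding_dialect == "all_same" and input_size % 32 != 0:
        raise ConfigurationError("all_same dialect requires input_size divisible by 32")
    vpad = "same" if padding_dialect == "all_same" else "valid"
    specs = [input_layer("input", (input_size, input_size, 3))]

    def cb(name, parent, ch, k, stride=1, padding="same"):
        return _conv_block(specs, name, parent, ch, k, stride, padding)

    # Stem
    x = cb("Conv1", "input", 32, 3, stride=2, padding=vpad)
    x = cb("Conv2", x, 32, 3, padding=vpad)
    x = cb("Conv3", x, 64, 3, padding="same")
    specs.append(maxpool("Pool1", x, 3, stride=2, padding=vpad))
    x = cb("Conv4", "Pool1", 80, 1, padding=vpad)
    x = cb("Conv5", x, 192, 3, padding=vpad)
    specs.append(maxpool("Pool2", x, 3, stride=2, padding=vpad))
    x = "Pool2"

    def mixed_a(name, parent, pool_ch):
        b0 = cb(f"{name}/b1x1", parent, 64, 1)
        b1 = cb(f"{name}/b5x5_1", parent, 48, 1)
        b1 = cb(f"{name}/b5x5_2", b1, 64, 5)
        b2 = cb(f"{name}/b3x3dbl_1", parent, 64, 1)
        b2 = cb(f"{name}/b3x3dbl_2", b2, 96, 3)
        b2 = cb(f"{name}/b3x3dbl_3", b2, 96, 3)
        specs.append(avgpool(f"{name}/pool", parent, 3, stride=1, padding="same"))
        b3 = cb(f"{name}/bpool", f"{name}/pool", pool_ch, 1)
        specs.append(concat(name, [b0, b1, b2, b3]))
        return name

    def mixed_reduce_a(name, parent):  # Mixed3
        b0 = cb(f"{name}/b3x3", parent, 384, 3, stride=2, padding=vpad)
        b1 = cb(f"{name}/b3x3dbl_1", parent, 64, 1)
        b1 = cb(f"{name}/b3x3dbl_2", b1, 96, 3)
        b1 = cb(f"{name}/b3x3dbl_3", b1, 96, 3, stride=2, padding=vpad)
        specs.append(maxpool(f"{name}/pool", parent, 3, stride=2, padding=vpad))
        specs.append(concat(name, [b0, b1, f"{name}/pool"]))
        return name

    def mixed_c(name, parent, c7):
        b0 = cb(f"{name}/b1x1", parent, 192, 1)
        b1 = cb(f"{name}/b7x7_1", parent, c7, 1)
        b1 = cb(f"{name}/b7x7_2", b1, c7, (1, 7))
        b1 = cb(f"{name}/b7x7_3", b1, 192, (7, 1))
        b2 = cb(f"{name}/b7x7dbl_1", parent, c7, 1)
        b2 = cb(f"{name}/b7x7dbl_2", b2, c7, (7, 1))
        b2 = cb(f"{name}/b7x7dbl_3", b2, c7, (1, 7))
        b2 = cb(f"{name}/b7x7dbl_4", b2, c7, (7, 1))
        b2 = cb(f"{name}/b7x7dbl_5", b2, 192, (1, 7))
        specs.append(avgpool(f"{name}/pool", parent, 3, stride=1, padding="same"))
        b3 = cb(f"{name}/bpool", f"{name}/pool", 192, 1)
        specs.append(concat(name, [b0, b1, b2, b3]))
        return name

    def mixed_reduce_b(name, parent):  # Mixed8
        b0 = cb(f"{name}/b3x3_1", parent, 192, 1)
        b0 = cb(f"{name}/b3x3_2", b0, 320, 3, stride=2, padding=vpad)
        b1 = cb(f"{name}/b7x7x3_1", parent, 192, 1)
        b1 = cb(f"{name}/b7x7x3_2", b1, 192, (1, 7))
        b1 = cb(f"{name}/b7x7x3_3", b1, 192, (7, 1))
        b1 = cb(f"{name}/b7x7x3_4", b1, 192, 3, stride=2, padding=vpad)
        specs.append(maxpool(f"{name}/pool", parent, 3, stride=2, padding=vpad))
        specs.append(concat(name, [b0, b1, f"{name}/pool"]))
        return name

    def mixed_e(name, parent):
        b0 = cb(f"{name}/b1x1", parent, 320, 1)
        b1 = cb(f"{name}/b3x3_1", parent, 384, 1)
        b1a = cb(f"{name}/b3x3_2a", b1, 384, (1, 3))
        b1b = cb(f"{name}/b3x3_2b", b1, 384, (3, 1))
        b2 = cb(f"{name}/b3x3dbl_1", parent, 448, 1)
        b2 = cb(f"{name}/b3x3dbl_2", b2, 384, 3)
        b2a = cb(f"{name}/b3x3dbl_3a", b2, 384, (1, 3))
        b2b = cb(f"{name}/b3x3dbl_3b", b2, 384, (3, 1))
        specs.append(avgpool(f"{name}/pool", parent, 3, stride=1, padding="same"))
        b3 = cb(f"{name}/bpool", f"{name}/pool", 192, 1)
        specs.append(concat(name, [b0, b1a, b1b, b2a, b2b, b3]))
        return name

    x = mixed_a("Mixed0", x, 32)
    x = mixed_a("Mixed1", x, 64)
    x = mixed_a("Mixed2", x, 64)
    x = mixed_reduce_a("Mixed3", x)
    x = mixed_c("Mixed4", x, 128)
    x = mixed_c("Mixed5", x, 160)
    x = mixed_c("Mixed6", x, 160)
    x = mixed_c("Mixed7", x, 192)
    x = mixed_reduce_b("Mixed8", x)
    x = mixed_e("Mixed9", x)
    x = mixed_e("Mixed10", x)
    specs.append(global_avg_pool("GAP", x))
    specs.append(dense("output", "GAP", n_classes, bias=True))
    specs.append(softmax("softmax", "output"))
    return build_graph(specs, init="zeros")


def truncate_at(graph, cut_layer, n_classes, head_init_seed=0):
    """Layer shaving: keep everything up to ``cut_layer`` (weights copied),
    attach a fresh GAP + dense head.  The original graph is untouched."""
    spec = graph.spec(cut_layer)
    if len(graph.shapes[cut_layer]) != 3:
        raise ConfigurationError(
            f"cut layer {cut_layer!r} has no spatial extent; cut before the GAP")
    # ancestor closure of the cut layer, in original topological order
    keep = {cut_layer}
    for s in reversed(graph.specs):
        if s.name in keep:
            keep.update(s.parents)
    specs = [s for s in graph.specs if s.name in keep]
    weights = {s.name: copy.deepcopy(graph.weights[s.name])
               for s in specs if s.name in graph.weights}
    for nm in ("GAP", "output", "softmax"):
        if nm in {s.name for s in specs}:
            raise ConfigurationError(f"cut layer retains reserved head layer {nm!r}")
    specs.append(global_avg_pool("GAP", cut_layer))
    specs.append(dense("output", "GAP", n_classes, bias=True))
    specs.append(softmax("softmax", "output"))
    new = build_graph(specs, init="random", seed=head_init_seed)
    rng = np.random.default_rng(head_init_seed)
    cin = new.shapes["GAP"][0]
    new.weights["output"]["W"] = rng.normal(0.0, np.sqrt(1.0 / cin), (cin, n_classes)).astype(DTYPE)
    new.weights["output"]["b"] = np.zeros(n_classes, dtype=DTYPE)
    for name, w in weights.items():
        new.weights[name] = w
    return new


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Adam + categorical cross-entropy training configuration.

    The default learning rate follows the source training protocol for the
    full-scale model; fixture-scale models typically train with a smaller
    rate.  Model selection keeps the epoch with the lowest validation loss.
    """

    optimizer: str = "adam"
    learning_rate: float = 0.05
    batch_size: int = 128
    epochs: int = 10
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    bn_momentum: float = 0.9

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


def _as_xy(split):
    if isinstance(split, tuple):
        x, y = split
        return np.asarray(x, dtype=DTYPE), np.asarray(y, dtype=int)
    x = np.stack([s.image for s in split]).astype(DTYPE)
    y = np.asarray([s.label for s in split], dtype=int)
    return x, y


def evaluate(graph, split, batch_size=256):
    """(cross-entropy loss, accuracy) of the softmax output on a split."""
    x, y = _as_xy(split)
    losses, hits = [], []
    for i in range(0, len(x), batch_size):
        probs = run_forward(graph, x[i:i + batch_size])[graph.output_name]
        p = np.clip(probs[np.arange(len(probs)), y[i:i + batch_size]], 1e-12, None)
        losses.append(-np.log(p))
        hits.append(probs.argmax(axis=1) == y[i:i + batch_size])
    return float(np.concatenate(losses).mean()), float(np.concatenate(hits).mean())


def train(graph, splits, config=None, freeze=None):
    """Train a copy of ``graph``; returns (best graph, history DataFrame).

    ``splits`` is anything with ``train``/``validation`` attributes or a
    dict with those keys (values: lists of samples or (X, y) tuples).
    ``freeze`` lists layer names whose weights and batchnorm statistics are
    left untouched.  The returned graph carries the weight snapshot with
    the lowest validation loss; a fixed seed makes the history reproducible.
    """
    import pandas as pd

    config = config or TrainConfig()
    freeze = set(freeze or ())
    for name in freeze:
        graph.spec(name)
    if isinstance(splits, dict):
        tr, va = splits["train"], splits["validation"]
    else:
        tr, va = splits.train, splits.validation
    xtr, ytr = _as_xy(tr)
    xva, yva = _as_xy(va)
    if len(xtr) == 0 or len(xva) == 0:
        raise ConfigurationError("empty training or validation split")
    g = graph.copy()
    n_classes = g.shapes[g.logit_name][0]
    update_stats = {s.name for s in g.specs if s.kind == "batchnorm"} - freeze
    rng = np.random.default_rng(config.seed)
    adam_m, adam_v, t = {}, {}, 0
    rows, best = [], (np.inf, None)
    for epoch in range(config.epochs):
        perm = rng.permutation(len(xtr))
        ep_loss, ep_hits = [], []
        for i in range(0, len(xtr), config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            state = run_forward(g, xb, training=True, update_stats=update_stats,
                                bn_momentum=config.bn_momentum)
            probs = state[g.output_name]
            onehot = np.eye(n_classes)[yb]
            p = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            loss = float(-np.log(p).mean())
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            ep_loss.append(loss)
            ep_hits.append(float((probs.argmax(axis=1) == yb).mean()))
            # fused softmax + cross-entropy gradient, seeded at the logits
            glogit = (probs - onehot) / len(yb)
            sig = backward(g, state, ("weighted", g.logit_name, glogit), param_grads=True)
            t += 1
            for lname, grads in sig["params"].items():
                if lname in freeze:
                    continue
                for pname, grad in grads.items():
                    key = (lname, pname)
                    m = adam_m.setdefault(key, np.zeros_like(grad))
                    v = adam_v.setdefault(key, np.zeros_like(grad))
                    m += (1 - config.beta1) * (grad - m)
                    v += (1 - config.beta2) * (grad * grad - v)
                    mhat = m / (1 - config.beta1 ** t)
                    vhat = v / (1 - config.beta2 ** t)
                    g.weights[lname][pname] -= (
                        config.learning_rate * mhat / (np.sqrt(vhat) + config.eps))
        val_loss, val_acc = evaluate(g, (xva, yva))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(ep_loss)),
                     "train_acc": float(np.mean(ep_hits)),
                     "val_loss": val_loss, "val_acc": val_acc})
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(g.weights))
    if best[1] is not None:
        g.weights = best[1]
    return g, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization: HDF5 weights + JSON architecture manifest
# ---------------------------------------------------------------------------

def save_graph(graph, weights_path, manifest_path):
    with h5py.File(weights_path, "w") as f:
        for lname, params in graph.weights.items():
            for pname, arr in params.items():
                f.create_dataset(f"{lname}/{pname}", data=arr)
    manifest = [{"name": s.name, "kind": s.kind, "hyper": s.hyper, "parents": list(s.parents)}
                for s in graph.specs]
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1)


def load_graph(weights_path, manifest_path):
    with open(manifest_path) as f:
        manifest = json.load(f)
    specs = []
    for m in manifest:
        hyper = dict(m["hyper"])
        for k in ("kernel", "pool", "shape"):
            if k in hyper:
                hyper[k] = tuple(hyper[k])
        specs.append(LayerSpec(m["name"], m["kind"], hyper, tuple(m["parents"])))
    weights = {}
    with h5py.File(weights_path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                lname, pname = name.rsplit("/", 1)
                weights.setdefault(lname, {})[pname] = np.asarray(obj, dtype=DTYPE)
        f.visititems(visit)
    return build_graph(specs, init="provided", weights=weights)
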