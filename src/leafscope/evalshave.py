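"""Quantitative evaluation of attention maps, misclassification inspection,
and the layer-shaving experiment series.

Attention maps are scored against binary lesion annotations with
mass-based sensitivity/specificity, thresholded IoU and the pointing game.
``misclassification_report`` tabulates each misclassified test image with
its top predictions, requested attention maps and a background-attention
statistic (heat mass outside the leaf).  ``shave_series`` truncates a
trained network at successively deeper layers, transfer-learns a fresh
GAP + dense head on each truncation, and reports parameters/accuracy/loss
per cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import attention as att
from .netcore import (TrainConfig, count_parameters, evaluate, run_forward,
                      train, truncate_at, ConfigurationError)


@dataclass
class OverlapMetrics:
    """Lesion-overlap scores of one attention map, all in [0, 1].

    sensitivity: heat mass inside the lesion mask / total heat mass (mass
    based, no binarization); specificity: 1 - mean heat per non-lesion
    pixel; iou: intersection-over-union of (map >= tau) with the mask;
    pointing_hit: whether the map's argmax pixel falls inside the mask.
    """

    sensitivity: float | None
    specificity: float
    iou: float
    pointing_hit: bool


def overlap_metrics(amap, mask, tau=0.5):
    values = amap.values if isinstance(amap, att.AttentionMap) else np.asarray(amap)
    mask = np.asarray(mask).astype(bool)
    if values.shape != mask.shape:
        raise ConfigurationError(
            f"map shape {values.shape} does not match mask shape {mask.shape}")
    total = values.sum()
    if mask.sum() == 0:
        sens = None
    else:
        sens = float(values[mask].sum() / total) if total > 0 else 0.0
    off = ~mask
    spec = 1.0 - float(values[off].mean()) if off.any() else 1.0
    binar = values >= tau
    union = (binar | mask).sum()
    iou = float((binar & mask).sum() / union) if union > 0 else 0.0
    hit = bool(mask.flat[int(values.argmax())])
    return OverlapMetrics(sens, spec, iou, hit)


def background_attention_fraction(amap, leaf_mask):
    """Fraction of heat mass lying outside the leaf region."""
    values = amap.values if isinstance(amap, att.AttentionMap) else np.asarray(amap)
    total = values.sum()
    if total == 0:
        return 0.0
    return float(values[~np.asarray(leaf_mask).astype(bool)].sum() / total)


_METHODS = {
    "gradcam": lambda g, im, j, kw: att.grad_cam_map(g, im, j, kw["layer"]),
    "guided": lambda g, im, j, kw: att.guided_backprop_map(g, im, j),
    "vanilla": lambda g, im, j, kw: att.vanilla_saliency(g, im, j),
    "ig": lambda g, im, j, kw: att.integrated_gradients_map(g, im, j),
}


def misclassification_report(graph, samples, methods=("gradcam", "guided"),
                             top_m=3, layer=None, include_correct=False):
    """Inspect (mis)classified samples with attention maps.

    Returns (DataFrame, {row index: {method: AttentionMap}}).  Each row
    carries the true label, the top_m predicted labels/probabilities and,
    when the sample has a leaf mask, the background-attention fraction of
    the first requested method.  With ``include_correct`` the table covers
    every sample and flags misclassification (useful for comparing the
    background statistic between correct and incorrect predictions).
    """
    x = np.stack([s.image for s in samples])
    y = np.asarray([s.label for s in samples])
    probs = run_forward(graph, x)[graph.output_name]
    pred = probs.argmax(axis=1)
    layer = layer or _default_cam_layer(graph)
    rows, maps = [], {}
    for i, s in enumerate(samples):
        wrong = pred[i] != y[i]
        if not (wrong or include_correct):
            continue
        top = np.argsort(-probs[i], kind="stable")[:top_m]
        row = {"index": i, "true_label": int(y[i]), "misclassified": bool(wrong),
               "top_labels": list(map(int, top)),
               "top_probs": [float(probs[i, j]) for j in top]}
        maps[i] = {m: _METHODS[m](graph, s.image, int(pred[i]), {"layer": layer})
                   for m in methods}
        if s.leaf_mask is not None and methods:
            row["background_attention"] = background_attention_fraction(
                maps[i][methods[0]], s.leaf_mask)
        rows.append(row)
    cols = ["index", "true_label", "misclassified", "top_labels", "top_probs",
            "background_attention"]
    frame = pd.DataFrame(rows, columns=cols if rows else cols[:5])
    return frame, maps


def _default_cam_layer(graph):
    spatial = [s.name for s in graph.specs if len(graph.shapes[s.name]) == 3
               and s.kind != "input"]
    return spatial[-1]


@dataclass
class ShaveReport:
    """Per-cut parameter totals and test metrics, plus the full-model row."""

    table: pd.DataFrame

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def shave_series(graph, cut_layers, splits, config=None, freeze_features=True,
                 head_init_seed=0, n_classes=None):
    """Truncate at each cut layer (ordered shallow -> deep), transfer-learn
    the fresh GAP + dense head (feature layers frozen by default), evaluate
    on the test split and count parameters.

    The returned table ends with a reference row for the full model.
    """
    if n_classes is None:
        n_classes = graph.shapes[graph.logit_name][0]
    # head-only transfer is a logistic fit on frozen GAP features: the default
    # budget is sized for convergence of that fit, not for feature learning
    config = config or TrainConfig(learning_rate=0.02, batch_size=32, epochs=30, seed=0)
    rows = []
    for cut in cut_layers:
        t = truncate_at(graph, cut, n_classes, head_init_seed=head_init_seed)
        freeze = ({s.name for s in t.specs if s.name not in ("GAP", "output", "softmax")}
                  if freeze_features else None)
        trained, hist = train(t, splits, config, freeze=freeze)
        loss, acc = evaluate(trained, splits.test)
        rows.append({"cut_layer": cut, "params": count_parameters(trained).total,
                     "test_acc": acc, "test_loss": loss, "epochs": len(hist)})
    floss, facc = evaluate(graph, splits.test)
    rows.append({"cut_layer": "<full>", "params": count_parameters(graph).total,
                 "test_acc": facc, "test_loss": floss, "epochs": 0})
    table = pd.DataFrame(rows)
    cuts = table[table.cut_layer != "<full>"].params.to_numpy()
    if not np.all(np.diff(cuts) > 0):
        raise ConfigurationError("cut layers must be ordered shallow to deep")
    return ShaveReport(table)


def parameter_reduction_percent(full_total, truncated_total):
    """100 * (1 - truncated/full): the parameter saving of a truncation."""
    return 100.0 * (1.0 - truncated_total / full_total)
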