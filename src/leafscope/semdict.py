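"""Visualization III: the semantic dictionary at the global-average-pooling layer.

Since the pre-softmax class score is the dot product of the GAP output
vector ``a`` with the head weights ``W[:, j]`` plus the bias ``b[j]``, each
summand ``c_k = a_k * W[k, j]`` is the *contribution score* of GAP neuron
``k`` to class ``j``: the scores conserve the logit exactly (sum_k c_k +
b_j = logit_j).  The dictionary ranks neurons by their mean contribution
over a set of same-class images and pairs the top contributors with their
feature-visualization renders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featviz import NeuronSelector, visualize_neuron
from .netcore import run_forward, ConfigurationError


@dataclass
class ContributionTable:
    """Per-GAP-neuron, per-class contribution scores for one GAP vector.

    ``scores[k, j] = a[k] * W[k, j]``; ``scores[:, j].sum() + bias[j]``
    reconstructs the pre-softmax logit of class j."""

    scores: np.ndarray
    bias: np.ndarray
    gap: np.ndarray

    def logits(self):
        return self.scores.sum(axis=0) + self.bias


@dataclass
class DictionaryEntry:
    neuron: int
    score: float
    target_class: int
    render: np.ndarray | None = None
    trace: np.ndarray | None = None


def contribution_scores(a, W, b, class_index=None):
    """Contribution table from a GAP vector; ``class_index`` selects one
    column (returned as a 1-D score vector) when given."""
    a = np.asarray(a, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape[0] != W.shape[0] or W.shape[1] != b.shape[0]:
        raise ConfigurationError(
            f"dimension mismatch: a {a.shape}, W {W.shape}, b {b.shape}")
    table = ContributionTable(a[:, None] * W, b, a)
    if class_index is None:
        return table
    return table.scores[:, class_index]


def gap_vectors(graph, images):
    """GAP activations for a list/array of images."""
    gap_name, _, _, _ = graph.gap_head()
    x = np.stack([np.asarray(im) for im in images])
    return run_forward(graph, x)[gap_name]


def contribution_table(graph, image):
    """Full per-neuron x per-class table for one image."""
    _, _, W, b = graph.gap_head()
    a = gap_vectors(graph, [image])[0]
    return contribution_scores(a, W, b)


def mean_contributions(graph, images, class_index):
    """Element-wise mean contribution score over images, ranked descending
    (ties broken by neuron index).  Returns a DataFrame (neuron, score)."""
    if len(images) == 0:
        raise ConfigurationError("empty image list")
    _, _, W, b = graph.gap_head()
    a = gap_vectors(graph, images)
    mean_scores = (a * W[:, class_index]).mean(axis=0)
    order = np.lexsort((np.arange(len(mean_scores)), -mean_scores))
    return pd.DataFrame({"neuron": order, "score": mean_scores[order]})


def cross_class_scores(graph, images, classes=None):
    """Mean contribution of every GAP neuron to every class (the bar-chart
    table): DataFrame indexed by neuron, one column per class."""
    _, _, W, b = graph.gap_head()
    a = gap_vectors(graph, images).mean(axis=0)
    classes = range(W.shape[1]) if classes is None else classes
    return pd.DataFrame({j: a * W[:, j] for j in classes})


def build_dictionary(graph, images, class_index, top_n=6, render=True,
                     featviz_config=None):
    """Top-n contributing GAP neurons for a class, each paired with its
    activation-maximization render on the GAP layer.

    Returns (entries, cross-class score table)."""
    _, _, W, b = graph.gap_head()
    if top_n > W.shape[0]:
        raise ConfigurationError("top_n exceeds the GAP dimension")
    ranked = mean_contributions(graph, images, class_index)
    gap_name = graph.gap_head()[0]
    cfg = dict(steps=256, lr=0.05, seed=0, pre_relu=True)
    cfg.update(featviz_config or {})
    entries = []
    for _, row in ranked.head(top_n).iterrows():
        k = int(row.neuron)
        entry = DictionaryEntry(k, float(row.score), class_index)
        if render:
            entry.render, entry.trace = visualize_neuron(
                graph, NeuronSelector(gap_name, k), **cfg)
        entries.append(entry)
    return entries, cross_class_scores(graph, images)


def dictionary_to_csv(entries, path):
    pd.DataFrame([{"neuron": e.neuron, "class": e.target_class, "mean_score": e.score}
                  for e in entries]).to_csv(path, index=False)
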