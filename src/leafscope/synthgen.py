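"""Synthetic leaf-disease imagery with ground-truth lesion masks.

Emulates the structure of single-leaf disease-classification datasets at toy
scale: one elliptical leaf on a uniform background, disease classes
distinguished by lesion color, texture and count, a healthy class with no
lesions, and a 6:2:2 train/validation/test split.  Each sample carries the
binary lesion mask recorded before pixel noise, playing the role of manual
lesion annotations in downstream attention-map evaluation.

The default task has four classes whose only discriminative feature is the
lesion pattern (healthy; large brown solid lesions; ringed lesions with a
yellow halo; small dark dense spots), echoing the phenotype variety of
northern leaf blight / early blight / leaf scorch symptoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .netcore import (TrainConfig, build_graph, conv2d, batchnorm, relu, maxpool,
                      avgpool, concat, dense, global_avg_pool, input_layer, softmax,
                      train, ConfigurationError)


@dataclass(frozen=True)
class ClassSpec:
    """Recipe for one synthetic disease class.

    Colors are RGB triples in [0, 1]; lesions are disks with radius drawn
    from ``lesion_radius`` (pixels) and count from ``lesion_count``;
    ``lesion_texture`` "ringed" draws a dark center with a lighter halo of
    the lesion color.  ``noise_sd`` is the Gaussian pixel-noise standard
    deviation applied after painting (then clipped to [0, 1]).
    """

    class_id: int
    name: str
    leaf_color: tuple
    lesion_color: tuple
    lesion_count: tuple = (0, 0)
    lesion_radius: tuple = (3, 6)
    lesion_texture: str = "solid"
    background_color: tuple = (0.45, 0.40, 0.35)
    noise_sd: float = 0.02

    def __post_init__(self):
        for c in (self.leaf_color, self.lesion_color, self.background_color):
            if not all(0.0 <= v <= 1.0 for v in c):
                raise ConfigurationError("colors must lie in [0, 1]")
        if self.lesion_count[0] > self.lesion_count[1]:
            raise ConfigurationError("lesion count range min > max")
        if self.lesion_radius[0] < 1:
            raise ConfigurationError("lesion radius must be >= 1 px")


@dataclass
class SyntheticSample:
    """Image + ground-truth lesion mask + label + generation provenance.

    ``leaf_mask`` marks the leaf region (used for the background-attention
    statistic of misclassification reports)."""

    image: np.ndarray
    mask: np.ndarray
    label: int
    spec: ClassSpec
    seed: int
    leaf_mask: np.ndarray | None = None


@dataclass
class DatasetSplits:
    train: list
    validation: list
    test: list

    def all_samples(self):
        return self.train + self.validation + self.test


def default_class_specs(noise_sd=0.02):
    """The 4-class color/texture/count-separable default task."""
    return [
        ClassSpec(0, "healthy", (0.20, 0.55, 0.20), (0.0, 0.0, 0.0),
                  lesion_count=(0, 0), noise_sd=noise_sd),
        ClassSpec(1, "brown_blight", (0.20, 0.55, 0.20), (0.42, 0.26, 0.10),
                  lesion_count=(3, 6), lesion_radius=(4, 7), noise_sd=noise_sd),
        ClassSpec(2, "ringed_spot", (0.20, 0.55, 0.20), (0.85, 0.75, 0.25),
                  lesion_count=(2, 4), lesion_radius=(5, 8),
                  lesion_texture="ringed", noise_sd=noise_sd),
        ClassSpec(3, "dark_speck", (0.20, 0.55, 0.20), (0.10, 0.08, 0.06),
                  lesion_count=(8, 14), lesion_radius=(2, 3), noise_sd=noise_sd),
    ]


def make_sample(spec, size=64, seed=0):
    """Render one leaf image: ellipse leaf, disk lesions clipped to the leaf,
    Gaussian noise; the lesion mask is recorded before noise."""
    if size < 32:
        raise ConfigurationError("image size must be >= 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2 + rng.uniform(-size * 0.04, size * 0.04)
    cx = size / 2 + rng.uniform(-size * 0.04, size * 0.04)
    ay = size * rng.uniform(0.32, 0.42)
    ax = size * rng.uniform(0.26, 0.38)
    theta = rng.uniform(0, np.pi)
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    leaf = (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0
    if spec.lesion_radius[1] >= min(ay, ax):
        raise ConfigurationError("lesion radius larger than the leaf")

    img = np.empty((size, size, 3))
    img[:] = np.asarray(spec.background_color)
    img[leaf] = np.asarray(spec.leaf_color)
    mask = np.zeros((size, size), dtype=bool)
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    ys, xs = np.nonzero(leaf)
    for _ in range(n_lesions):
        r = float(rng.uniform(spec.lesion_radius[0], spec.lesion_radius[1]))
        i = int(rng.integers(len(ys)))
        ly, lx = ys[i], xs[i]
        d2 = (yy - ly) ** 2 + (xx - lx) ** 2
        disk = (d2 <= r * r) & leaf
        if spec.lesion_texture == "ringed":
            center = (d2 <= (r / 2) ** 2) & leaf
            img[disk] = np.asarray(spec.lesion_color)          # halo
            img[center] = np.asarray(spec.lesion_color) * 0.35  # dark center
        else:
            img[disk] = np.asarray(spec.lesion_color)
        mask |= disk
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SyntheticSample(img, mask.astype(np.uint8), spec.class_id, spec, seed,
                           leaf_mask=leaf.astype(np.uint8))


def _child_seed(seed, class_id, index):
    ss = np.random.SeedSequence(seed, spawn_key=(class_id, index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_dataset(specs, n_per_class=40, ratio=(6, 2, 2), size=64, seed=0):
    """Generate ``n_per_class`` samples per class and split them.

    Split sizes per class: floor(n * train_frac) for train, then
    floor(n * val_frac) for validation, remainder to test — so n=10 under
    the default 6:2:2 ratio yields exactly 6/2/2.
    """
    if not specs:
        raise ConfigurationError("empty class spec list")
    if n_per_class < 5:
        raise ConfigurationError("need at least 5 samples per class")
    total = sum(ratio)
    rng = np.random.default_rng(seed)
    splits = DatasetSplits([], [], [])
    for spec in specs:
        samples = [make_sample(spec, size=size, seed=_child_seed(seed, spec.class_id, i))
                   for i in range(n_per_class)]
        order = rng.permutation(n_per_class)
        n_tr = int(np.floor(n_per_class * ratio[0] / total))
        n_va = int(np.floor(n_per_class * ratio[1] / total))
        splits.train += [samples[i] for i in order[:n_tr]]
        splits.validation += [samples[i] for i in order[n_tr:n_tr + n_va]]
        splits.test += [samples[i] for i in order[n_tr + n_va:]]
    return splits


# ---------------------------------------------------------------------------
# Fixture classifiers
# ---------------------------------------------------------------------------

def tiny_cnn_specs(n_classes, size=64):
    """3 conv blocks + GAP + dense head; layer names Conv1..Conv3."""
    return [
        input_layer("input", (size, size, 3)),
        conv2d("Conv1/conv", "input", 8, 3, padding="same"),
        batchnorm("Conv1/bn", "Conv1/conv"),
        relu("Conv1", "Conv1/bn"),
        maxpool("Pool1", "Conv1", 2),
        conv2d("Conv2/conv", "Pool1", 16, 3, padding="same"),
        batchnorm("Conv2/bn", "Conv2/conv"),
        relu("Conv2", "Conv2/bn"),
        maxpool("Pool2", "Conv2", 2),
        conv2d("Conv3/conv", "Pool2", 16, 3, padding="same"),
        batchnorm("Conv3/bn", "Conv3/conv"),
        relu("Conv3", "Conv3/bn"),
        global_avg_pool("GAP", "Conv3"),
        dense("output", "GAP", n_classes),
        softmax("softmax", "output"),
    ]


def inception_mini_specs(n_classes, size=64):
    """One stem conv + one inception-style multi-branch module + GAP head."""
    specs = [
        input_layer("input", (size, size, 3)),
        conv2d("Conv1/conv", "input", 8, 3, stride=2, padding="same"),
        batchnorm("Conv1/bn", "Conv1/conv"),
        relu("Conv1", "Conv1/bn"),
    ]
    for br, (ch, k) in {"b1x1": (8, 1), "b3x3": (8, 3), "b5x5": (4, 5)}.items():
        specs += [conv2d(f"Mixed0/{br}/conv", "Conv1", ch, k, padding="same"),
                  batchnorm(f"Mixed0/{br}/bn", f"Mixed0/{br}/conv"),
                  relu(f"Mixed0/{br}", f"Mixed0/{br}/bn")]
    specs.append(avgpool("Mixed0/pool", "Conv1", 3, stride=1, padding="same"))
    specs += [conv2d("Mixed0/bpool/conv", "Mixed0/pool", 4, 1),
              batchnorm("Mixed0/bpool/bn", "Mixed0/bpool/conv"),
              relu("Mixed0/bpool", "Mixed0/bpool/bn")]
    specs.append(concat("Mixed0", ["Mixed0/b1x1", "Mixed0/b3x3", "Mixed0/b5x5", "Mixed0/bpool"]))
    specs += [global_avg_pool("GAP", "Mixed0"),
              dense("output", "GAP", n_classes),
              softmax("softmax", "output")]
    return specs


def make_fixture_model(splits, arch="tiny_cnn", config=None, seed=0):
    """Train a small GAP-headed classifier on synthetic splits.

    Returns (trained graph, history).  The GAP + dense head is guaranteed
    (required by the semantic dictionary and the Grad-CAM/CAM equivalence).
    """
    n_classes = len({s.label for s in splits.train})
    size = splits.train[0].image.shape[0]
    if arch == "tiny_cnn":
        specs = tiny_cnn_specs(n_classes, size)
    elif arch == "inception_mini":
        specs = inception_mini_specs(n_classes, size)
    else:
        raise ConfigurationError(f"unknown fixture architecture {arch!r} "
                                 "(GAP-headed 'tiny_cnn' or 'inception_mini')")
    graph = build_graph(specs, init="random", seed=seed)
    config = config or TrainConfig(learning_rate=0.01, batch_size=32, epochs=15, seed=seed)
    trained, history = train(graph, splits, config)
    return trained, history


# ---------------------------------------------------------------------------
# On-disk layout: PNG images + masks, labels CSV, manifest JSON
# ---------------------------------------------------------------------------

def save_dataset(splits, out_dir):
    from PIL import Image
    import pandas as pd

    out = Path(out_dir)
    rows = []
    for split_name in ("train", "validation", "test"):
        d = out / split_name
        d.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(getattr(splits, split_name)):
            img_path = d / f"{i:04d}_class{s.label}.png"
            msk_path = d / f"{i:04d}_class{s.label}_mask.png"
            Image.fromarray((s.image * 255).round().astype(np.uint8)).save(img_path)
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(msk_path)
            rows.append({"split": split_name, "image": str(img_path.relative_to(out)),
                         "mask": str(msk_path.relative_to(out)),
                         "label": s.label, "seed": s.seed})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    manifest = {"classes": sorted({r["label"] for r in rows}),
                "counts": {k: sum(r["split"] == k for r in rows)
                           for k in ("train", "validation", "test")}}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return out / "labels.csv"
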