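"""Synthetic feature-bag datasets with planted regions of interest.

The generator emulates the abstraction level at which MIL aggregators see a
slide: each bag is a set of patch feature vectors on a patch-grid lattice.
Negative ("normal") bags draw every instance from an isotropic Gaussian
background N(mu_0, sigma^2 I). A positive bag of class ``c`` plants
``round(rho * N)`` key instances drawn from N(mu_c, sigma^2 I) with
``||mu_c - mu_0|| = delta``; the key instances occupy a contiguous
rectangular block of the lattice and the emitted polygon annotation covers
exactly that block, so the annotation-derived patch labels reproduce the
planted ones. ``delta`` (the class-mean separation) controls task
difficulty; at the default ``delta=6, sigma=1`` the instance-level Bayes
error is Phi(-delta/2) ~ 0.13%, i.e. key instances are nearly separable,
mirroring a well-posed tumor-detection task.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .bagcore import (
    AnnotationSet,
    InstanceBag,
    write_annotations,
    write_bag,
    write_label_table,
    read_annotations,
    read_bag,
    read_label_table,
)

__all__ = ["SynthConfig", "make_dataset", "make_fixture", "write_dataset", "load_dataset"]


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generation parameters for a synthetic bag dataset.

    ``classes=2`` is binary tumor-vs-normal; ``classes>2`` emulates
    subtyping with class 0 as the normal class and one shifted feature
    mean per tumor class. ``grid_side`` is the edge of the square patch
    lattice each bag lives on (must hold ``n_max`` patches).

    The default scale — 200 bags per class with 32-64 instances each —
    emulates the slide counts of the public benchmarks (a few hundred
    training slides) at reduced bag size, so that the fixed 50-epoch
    protocol sees a comparable number of optimizer steps.
    """

    n_bags_per_class: int = 200
    classes: int = 2
    n_min: int = 32
    n_max: int = 64
    feature_dim: int = 1024
    key_fraction: float = 0.2    # rho: fraction of key instances in positive bags
    separation: float = 6.0      # delta: ||mu_c - mu_0||
    noise_sd: float = 1.0
    patch_size: int = 256
    grid_side: int = 10
    scattered: bool = False      # stress mode: keys not spatially contiguous
    seed: int = 0

    def validate(self) -> None:
        if self.classes < 2:
            raise ConfigError("need at least 2 classes")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ConfigError("invalid instances_per_bag range")
        if not (0 < self.key_fraction <= 1):
            raise ConfigError("key_fraction must be in (0, 1] for positive classes")
        if round(self.key_fraction * self.n_min) < 1:
            raise ConfigError("key_fraction * n_min < 1: positive bags could lack key instances")
        if self.grid_side * self.grid_side < self.n_max:
            raise ConfigError("grid_side^2 must be >= n_max")
        if self.separation < 0 or self.noise_sd <= 0:
            raise ConfigError("separation must be >= 0 and noise_sd > 0")
        if self.classes - 1 > self.feature_dim:
            raise ConfigError("feature_dim too small for the number of positive classes")


def _class_means(cfg: SynthConfig) -> np.ndarray:
    """Row c is mu_c; mu_0 = 0, positive classes shifted along distinct axes."""
    means = np.zeros((cfg.classes, cfg.feature_dim))
    for c in range(1, cfg.classes):
        means[c, c - 1] = cfg.separation
    return means


def _key_block_cells(rng: np.random.Generator, cfg: SynthConfig, k: int) -> np.ndarray:
    """Row-major cells of a compact rectangular block holding k lattice cells."""
    w = int(np.ceil(np.sqrt(k)))
    h = int(np.ceil(k / w))
    if w > cfg.grid_side or h > cfg.grid_side:
        raise ConfigError("key block does not fit the lattice; increase grid_side")
    bx = int(rng.integers(0, cfg.grid_side - w + 1))
    by = int(rng.integers(0, cfg.grid_side - h + 1))
    cells = [(bx + i % w, by + i // w) for i in range(k)]
    return np.array(cells, dtype=np.int64)


def _cells_polygon(cells: np.ndarray, patch_size: int) -> Polygon:
    squares = [
        box(x * patch_size, y * patch_size, (x + 1) * patch_size, (y + 1) * patch_size)
        for x, y in cells
    ]
    return unary_union(squares)


def make_dataset(cfg: SynthConfig) -> tuple[list[InstanceBag], list[AnnotationSet], pd.DataFrame]:
    """Generate bags, matching annotations and a slide-label table.

    The label table assigns a 60/15/25 train/val/test split, stratified by
    class and deterministic in ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    means = _class_means(cfg)
    bags: list[InstanceBag] = []
    anns: list[AnnotationSet] = []
    rows = []

    all_cells = np.array(
        [(x, y) for y in range(cfg.grid_side) for x in range(cfg.grid_side)], dtype=np.int64
    )

    for c in range(cfg.classes):
        for b in range(cfg.n_bags_per_class):
            slide_id = f"synth_c{c}_b{b:03d}"
            n = int(rng.integers(cfg.n_min, cfg.n_max + 1))
            k = int(round(cfg.key_fraction * n)) if c > 0 else 0
            regions: list[tuple[str, Polygon]] = []
            if k > 0:
                if cfg.scattered:
                    idx = rng.choice(len(all_cells), size=k, replace=False)
                    key_cells = all_cells[idx]
                    regions = [
                        (f"class_{c}", _cells_polygon(key_cells[i:i + 1], cfg.patch_size))
                        for i in range(k)
                    ]
                else:
                    key_cells = _key_block_cells(rng, cfg, k)
                    regions = [(f"class_{c}", _cells_polygon(key_cells, cfg.patch_size))]
                key_set = {tuple(cell) for cell in map(tuple, key_cells)}
                rest = np.array([cell for cell in all_cells if tuple(cell) not in key_set])
                idx = rng.choice(len(rest), size=n - k, replace=False)
                cells = np.vstack([key_cells, rest[idx]])
                labels = np.concatenate([np.ones(k, np.int8), np.zeros(n - k, np.int8)])
            else:
                idx = rng.choice(len(all_cells), size=n, replace=False)
                cells = all_cells[idx]
                labels = np.zeros(n, np.int8)

            feats = rng.normal(0.0, cfg.noise_sd, size=(n, cfg.feature_dim))
            feats[labels == 1] += means[c]
            feats[labels == 0] += means[0]

            bags.append(
                InstanceBag(
                    slide_id=slide_id,
                    features=feats.astype(np.float32),
                    coords=cells * cfg.patch_size,
                    patch_size=cfg.patch_size,
                    bag_label=c,
                    patch_labels=labels,
                )
            )
            anns.append(AnnotationSet(slide_id=slide_id, regions=regions))
            rows.append({"slide_id": slide_id, "label": c})

    df = pd.DataFrame(rows)
    df["split"] = _stratified_split(df["label"].to_numpy(), cfg.seed)
    return bags, anns, df


def _stratified_split(labels: np.ndarray, seed: int,
                      fractions: tuple[float, float, float] = (0.6, 0.15, 0.25)) -> list[str]:
    rng = np.random.default_rng(seed + 1)
    split = np.empty(len(labels), dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_val = min(n_val, n - n_train)
        split[idx[:n_train]] = "train"
        split[idx[n_train:n_train + n_val]] = "val"
        split[idx[n_train + n_val:]] = "test"
    return list(split)


# ---------------------------------------------------------------------------
# pinned fixtures

_FIXTURES = {
    "tiny_binary": SynthConfig(
        n_bags_per_class=10, classes=2, n_min=32, n_max=64, feature_dim=64,
        grid_side=8, seed=20240901,
    ),
    "tiny_multiclass": SynthConfig(
        n_bags_per_class=3, classes=7, n_min=32, n_max=64, feature_dim=64,
        grid_side=8, seed=20240902,
    ),
}


def make_fixture(name: str):
    """Small pinned datasets used by the test suite.

    ``tiny_binary``: 20 bags, 10 per class. ``tiny_multiclass``: 7-class
    subtyping in the spirit of a canine cutaneous tumor panel (one normal
    class plus six tumor classes), 21 bags. Both use a reduced feature
    dimension so unit tests train in seconds.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return make_dataset(_FIXTURES[name])


def dataset_checksum(bags: list[InstanceBag]) -> str:
    """SHA-256 over feature bytes, coords and labels, order-sensitive."""
    h = hashlib.sha256()
    for bag in bags:
        h.update(bag.slide_id.encode())
        h.update(bag.features.tobytes())
        h.update(bag.coords.tobytes())
        h.update(bytes([bag.bag_label]))
        if bag.patch_labels is not None:
            h.update(bag.patch_labels.tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# on-disk layout: bags/<id>.h5, annotations/<id>.geojson, labels.csv


def write_dataset(bags, anns, labels, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "bags").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)
    for bag in bags:
        write_bag(bag, outdir / "bags" / f"{bag.slide_id}.h5")
    for ann in anns:
        write_annotations(ann, outdir / "annotations" / f"{ann.slide_id}.geojson")
    write_label_table(labels, outdir / "labels.csv")


def load_dataset(indir: str | Path):
    indir = Path(indir)
    labels = read_label_table(indir / "labels.csv")
    bags, anns = [], []
    for sid in labels["slide_id"]:
        bags.append(read_bag(indir / "bags" / f"{sid}.h5"))
        ann_path = indir / "annotations" / f"{sid}.geojson"
        anns.append(read_annotations(ann_path) if ann_path.exists()
                    else AnnotationSet(slide_id=sid))
    return bags, anns, labels
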