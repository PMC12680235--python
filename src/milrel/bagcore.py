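"""Core domain types and I/O for patch-feature bags, annotations and labels.

A whole-slide image enters the pipeline as an :class:`InstanceBag`: the
matrix of patch feature vectors extracted from its tessellation, the grid
coordinates of each patch (top-left corner, level-0 pixels) and the
slide-level label. Region annotations are labeled polygons in the same
pixel coordinate frame (:class:`AnnotationSet`), and
:func:`assign_patch_labels` turns them into the binary per-patch ground
truth against which patch scores are evaluated.

File formats:

* bags — HDF5 with datasets ``features`` (N x d, float32) and ``coords``
  (N x 2, int64), attributes ``slide_id``, ``patch_size``, ``level``,
  ``bag_label`` and optionally dataset ``patch_labels``;
* annotations — GeoJSON FeatureCollection of Polygons, class name in
  ``properties.classification``;
* slide labels — CSV with columns ``slide_id,label,split``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box, shape, mapping


class BagFormatError(ValueError):
    """A bag/annotation file is missing a field or has inconsistent shapes."""


class ScoreChannel(str, Enum):
    """What kind of per-patch score a model emitted."""

    attention = "attention"   # convex weights on the simplex
    patch_prob = "patch_prob"  # per-patch class probability in [0, 1]
    selection = "selection"    # (soft) indicator of max-selected patches


@dataclass
class InstanceBag:
    """One slide's bag of patch features.

    Parameters
    ----------
    slide_id
        Unique slide identifier.
    features
        ``(N, d)`` float matrix of patch feature vectors.
    coords
        ``(N, 2)`` integer matrix; top-left corner of each patch in level-0
        pixels, ``(x, y)``.
    patch_size
        Patch edge length in level-0 pixels.
    bag_label
        Slide-level class index.
    patch_labels
        Optional length-``N`` binary vector of ground-truth patch labels.
    """

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    patch_size: int = 256
    bag_label: int = 0
    patch_labels: np.ndarray | None = None
    level: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.features.ndim != 2 or self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise BagFormatError("features must be (N, d) and coords (N, 2)")
        n = self.features.shape[0]
        if n < 1:
            raise BagFormatError("bag must contain at least one instance")
        if self.coords.shape[0] != n:
            raise BagFormatError("coords length does not match features")
        if (self.coords < 0).any():
            raise BagFormatError("coords must be non-negative")
        if len(np.unique(self.coords, axis=0)) != n:
            raise BagFormatError("coords must be unique")
        if self.patch_labels is not None:
            self.patch_labels = np.asarray(self.patch_labels, dtype=np.int8)
            if self.patch_labels.shape != (n,):
                raise BagFormatError("patch_labels length does not match features")
            if not np.isin(self.patch_labels, (0, 1)).all():
                raise BagFormatError("patch_labels must be binary")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]


@dataclass
class AnnotationSet:
    """Labeled region polygons for one slide, level-0 pixel coordinates."""

    slide_id: str
    regions: list[tuple[str, Polygon]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for cls, poly in self.regions:
            if not isinstance(poly, Polygon):
                poly = Polygon(poly)
            if len(poly.exterior.coords) < 4:  # closed ring of >=3 vertices
                raise BagFormatError("polygon needs at least 3 vertices")
            if not poly.is_valid:
                raise BagFormatError(f"polygon for class {cls!r} is not simple")
            cleaned.append((str(cls), poly))
        self.regions = cleaned

    @property
    def classes(self) -> list[str]:
        return sorted({cls for cls, _ in self.regions})


@dataclass
class PatchScoreSet:
    """Per-patch scores emitted by a model for one slide."""

    slide_id: str
    scores: np.ndarray
    channel: ScoreChannel
    class_context: int = 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.channel = ScoreChannel(self.channel)
        if self.scores.ndim != 1:
            raise BagFormatError("scores must be a vector")
        if self.channel is ScoreChannel.attention:
            if abs(self.scores.sum() - 1.0) > 1e-6:
                raise BagFormatError("attention scores must sum to 1")
        elif ((self.scores < -1e-12) | (self.scores > 1 + 1e-12)).any():
            raise BagFormatError(f"{self.channel.value} scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# bag files


def write_bag(bag: InstanceBag, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int64))
        if bag.patch_labels is not None:
            f.create_dataset("patch_labels", data=bag.patch_labels.astype(np.int8))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patch_size"] = int(bag.patch_size)
        f.attrs["level"] = int(bag.level)
        f.attrs["bag_label"] = int(bag.bag_label)


def read_bag(path: str | Path) -> InstanceBag:
    with h5py.File(path, "r") as f:
        for name in ("features", "coords"):
            if name not in f:
                raise BagFormatError(f"bag file missing dataset {name!r}")
        feats = f["features"][...]
        coords = f["coords"][...]
        labels = f["patch_labels"][...] if "patch_labels" in f else None
        return InstanceBag(
            slide_id=str(f.attrs.get("slide_id", Path(path).stem)),
            features=feats,
            coords=coords,
            patch_size=int(f.attrs.get("patch_size", 256)),
            level=int(f.attrs.get("level", 0)),
            bag_label=int(f.attrs.get("bag_label", 0)),
            patch_labels=labels,
        )


# ---------------------------------------------------------------------------
# annotation files


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"classification": cls},
        }
        for cls, poly in ann.regions
    ]
    doc = {"type": "FeatureCollection", "slide_id": ann.slide_id, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_annotations(path: str | Path) -> AnnotationSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise BagFormatError("annotation file is not a GeoJSON FeatureCollection")
    regions = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        cls = feat.get("properties", {}).get("classification", "region")
        regions.append((cls, geom))
    return AnnotationSet(slide_id=str(doc.get("slide_id", Path(path).stem)), regions=regions)


# ---------------------------------------------------------------------------
# label tables


def write_label_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = {"slide_id", "label", "split"} - set(df.columns)
    if missing:
        raise BagFormatError(f"label table missing columns {sorted(missing)}")
    df.to_csv(path, index=False)


def read_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"slide_id": str, "split": str})
    missing = {"slide_id", "label", "split"} - set(df.columns)
    if missing:
        raise BagFormatError(f"label table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# patch-label assignment


def assign_patch_labels(
    bag: InstanceBag,
    ann: AnnotationSet,
    rule: str = "center_in",
    classes: Sequence[str] | None = None,
) -> np.ndarray:
    """Binary patch labels from region polygons.

    A patch footprint is the half-open square ``[x, x + patch_size) x
    [y, y + patch_size)``. Under ``rule="center_in"`` (default) a patch is
    positive iff its center point lies inside (or on the boundary of) any
    region polygon; under ``rule="any_overlap"`` a positive-area
    intersection with any polygon suffices. A patch touching no region is
    labeled 0; a slide with no regions yields all zeros.

    Parameters
    ----------
    classes
        Optional subset of annotation class names to consider; by default a
        polygon of any class marks patches positive.
    """
    if bag.slide_id != ann.slide_id:
        raise ValueError(
            f"bag slide_id {bag.slide_id!r} != annotation slide_id {ann.slide_id!r}")
    if rule not in ("center_in", "any_overlap"):
        raise ValueError(f"unknown rule {rule!r}")
    regions = [poly for cls, poly in ann.regions if classes is None or cls in classes]
    labels = np.zeros(bag.n_instances, dtype=np.int8)
    if not regions:
        return labels
    half = bag.patch_size / 2.0
    for i, (x, y) in enumerate(bag.coords):
        if rule == "center_in":
            pt = Point(x + half, y + half)
            hit = any(poly.intersects(pt) for poly in regions)
        else:
            foot = box(x, y, x + bag.patch_size, y + bag.patch_size)
            hit = any(poly.intersection(foot).area > 0 for poly in regions)
        labels[i] = 1 if hit else 0
    return labels
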