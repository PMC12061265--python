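"""Marker-ion segmentation of a section into ROIs, and per-label statistics.

A small set of proteoform ion images with distinct regional distributions
(e.g. a striatal, a thalamic and a hippocampal marker) defines the regions:
each image is scaled to its own maximum and every pixel is assigned to the
argmax marker when the winning scaled value reaches ``min_fraction``,
otherwise it stays unassigned.  This automates, deterministically, the ROI
drawing that is usually done by hand on marker images; hand-drawn masks can
still be supplied through the dataset's ROI mask to bypass this module.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msio import IonImage

__all__ = ["SegmentationMap", "segment_by_markers", "subregion_stats", "UNASSIGNED"]

UNASSIGNED = ""


@dataclass
class SegmentationMap:
    """Per-pixel ROI label (or unassigned) with the winning-marker score."""

    labels: np.ndarray      # (rows, cols) str
    scores: np.ndarray      # (rows, cols) winning scaled marker value
    markers: tuple[str, ...]
    min_fraction: float

    def label_set(self) -> list[str]:
        return sorted(set(self.labels.reshape(-1).tolist()) - {UNASSIGNED})


def segment_by_markers(
    images: dict[str, IonImage], min_fraction: float = 0.2
) -> SegmentationMap:
    """Assign each pixel to the region whose scaled marker image wins there.

    Ties break by marker insertion order (first wins), which makes the map
    deterministic.  Raising ``min_fraction`` can only shrink regions.
    """
    if not images:
        raise ValueError("empty marker set")
    labels = list(images)
    shapes = {im.values.shape for im in images.values()}
    if len(shapes) != 1:
        raise ValueError(f"marker image grids differ: {shapes}")
    stack = np.stack([images[lab].scaled() for lab in labels])
    win = stack.argmax(axis=0)           # first marker wins ties
    score = stack.max(axis=0)
    out = np.full(win.shape, UNASSIGNED, dtype="<U12")
    assigned = score >= min_fraction
    for i, lab in enumerate(labels):
        out[(win == i) & assigned] = lab
    return SegmentationMap(labels=out, scores=score, markers=tuple(labels),
                           min_fraction=min_fraction)


def subregion_stats(
    image: IonImage, segmap: SegmentationMap | np.ndarray
) -> pd.DataFrame:
    """Distribution summary of an ion image per segmented label.

    Returns one row per non-empty label: n, mean, sd, median, q1, q3.
    Labels with zero pixels are omitted.
    """
    labels = segmap.labels if isinstance(segmap, SegmentationMap) else segmap
    if labels.shape != image.values.shape:
        raise ValueError("segmentation and image grids differ")
    rows = []
    for lab in sorted(set(labels.reshape(-1).tolist()) - {UNASSIGNED}):
        vals = image.values[labels == lab]
        if vals.size == 0:
            continue
        rows.append(
            (
                lab, int(vals.size), float(vals.mean()),
                float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                float(np.median(vals)),
                float(np.percentile(vals, 25)), float(np.percentile(vals, 75)),
            )
        )
    return pd.DataFrame(rows, columns=["label", "n", "mean", "sd", "median", "q1", "q3"])
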