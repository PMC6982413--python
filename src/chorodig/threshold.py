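"""Color-threshold classification backend.

A lighter alternative to segmentation + random forest: every pixel within
a per-band tolerance of a legend color is assigned that class directly;
the leftover "holes" (blurred boundary pixels matching no legend color)
are then filled.  A hole enclosed by a single class takes that class as a
whole; a hole touching several classes — typically a band of mixed colors
along a blurred class boundary — is resolved pixel by pixel, each pixel
taking the touching class nearest its own color (ties: longest shared
hole boundary, then lowest class id), so the band splits along the true
boundary instead of collapsing to one side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .classify import PROV_RULE, ClassifiedMap
from .legend import Legend
from .segmentation import _prepare_pixels


class LegendColorOverlapError(ValueError):
    """Legend colors are closer than twice the matching tolerance."""


def _check_separation(legend: Legend, tolerance: float) -> None:
    classes = list(legend)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            dist = max(abs(x - y) for x, y in zip(a.color, b.color))
            if dist <= 2 * tolerance:
                raise LegendColorOverlapError(
                    f"classes {a.class_id} and {b.class_id} are {dist} apart in "
                    f"max-band distance; need > {2 * tolerance} for tolerance "
                    f"{tolerance}"
                )


def color_threshold_segment(
    img, legend: Legend, tolerance: float = 30.0
) -> ClassifiedMap:
    """Classify pixels by nearest legend color within a max-band tolerance.

    Requires legend colors pairwise separated by more than twice the
    tolerance, so a pixel matches at most one class.  Unmatched pixels are
    filled per the hole rules above; pixels with no classified neighbor at
    all (and invalid pixels) become no-data.
    """
    _check_separation(legend, tolerance)
    pixels, mask, transform, crs = _prepare_pixels(img)
    h, w = pixels.shape[:2]
    px = pixels.astype(np.int16)

    class_ids = legend.class_ids
    dist = np.empty((len(class_ids), h, w), dtype=np.int16)
    for k, cid in enumerate(class_ids):
        color = np.asarray(legend[cid].color, dtype=np.int16)
        dist[k] = np.abs(px - color).max(axis=2)
    nearest = dist.argmin(axis=0)
    mindist = dist.min(axis=0)
    assigned = (mindist <= tolerance) & mask
    classes = np.full((h, w), legend.nodata_id, dtype=np.int16)
    lut = np.asarray(class_ids, dtype=np.int16)
    classes[assigned] = lut[nearest[assigned]]

    # fill holes: connected components of unassigned-but-valid pixels
    holes = (~assigned) & mask
    if holes.any():
        comp = cc_label(holes, connectivity=1)
        n_comp = comp.max()
        # shared boundary length (pixel edges) between each hole and each class
        boundary: dict[int, dict[int, int]] = {c: {} for c in range(1, n_comp + 1)}
        for axis, (sl_a, sl_b) in enumerate((
            ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
            ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
        )):
            for first, second in ((sl_a, sl_b), (sl_b, sl_a)):
                hc = comp[first]
                nc = classes[second]
                na = assigned[second]
                m = (hc > 0) & na
                if not m.any():
                    continue
                for c, cl in zip(hc[m].tolist(), nc[m].tolist()):
                    d = boundary[c]
                    d[cl] = d.get(cl, 0) + 1
        # per-component pixel index lists without one mask pass per component
        flat_comp = comp.ravel()
        order = np.argsort(flat_comp, kind="stable")
        sorted_comp = flat_comp[order]
        starts = np.searchsorted(sorted_comp, np.arange(1, n_comp + 2))
        flat_classes = classes.ravel()
        flat_px = px.reshape(-1, 3)
        for c in range(1, n_comp + 1):
            touching = boundary[c]
            idx = order[starts[c - 1]: starts[c]]
            if not touching:
                continue  # stays no-data
            if len(touching) == 1:
                flat_classes[idx] = next(iter(touching))
                continue
            # a hole touching several classes (typically a blurred boundary
            # band) is resolved pixel by pixel: each pixel takes the
            # touching class nearest to its own color; ties go to the class
            # with the longest shared hole boundary, then the lowest id
            cand = sorted(touching, key=lambda cid: (-touching[cid], cid))
            dists = np.stack([
                np.abs(flat_px[idx] - np.asarray(legend[cid].color, np.int16))
                .max(axis=1)
                for cid in cand
            ])
            flat_classes[idx] = np.asarray(cand, np.int16)[dists.argmin(axis=0)]
        classes = flat_classes.reshape(h, w)

    # object layer: connected same-class regions
    valid = mask & (classes != legend.nodata_id)
    lab = cc_label(np.where(valid, classes, -1), connectivity=1, background=-1)
    labels = lab.astype(np.int32)
    labels[~valid] = 0
    obj_ids = np.unique(labels[labels > 0])
    if obj_ids.size:
        # each object is class-uniform by construction
        first_idx = {}
        flat_lab = labels.ravel()
        flat_cls = classes.ravel()
        order = np.argsort(flat_lab, kind="stable")
        sorted_lab = flat_lab[order]
        starts = np.searchsorted(sorted_lab, obj_ids)
        obj_cls = flat_cls[order[starts]]
        object_classes = pd.Series(obj_cls.astype(int), index=obj_ids.astype(int))
    else:
        object_classes = pd.Series(dtype=int)
    prov = pd.Series(PROV_RULE, index=object_classes.index, dtype=object)
    return ClassifiedMap(classes, labels, object_classes, prov,
                         transform, crs, legend.nodata_id)


class ColorThresholdSegmenter:
    """Estimator-style front end for the color-threshold backend."""

    def __init__(self, legend: Legend | None = None, tolerance: float = 30.0):
        self.legend = legend
        self.tolerance = tolerance

    def get_params(self, deep: bool = True) -> dict:
        return {"legend": self.legend, "tolerance": self.tolerance}

    def set_params(self, **params) -> "ColorThresholdSegmenter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "ColorThresholdSegmenter":
        return self

    def transform(self, image) -> ClassifiedMap:
        if self.legend is None:
            raise ValueError("a legend is required")
        return color_threshold_segment(image, self.legend, self.tolerance)

    segment = transform
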