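"""Rule-based cleanup of classified maps.

Choropleth scans carry cartographic ink — black unit borders and label
text — that must not survive into the class layer.  Small black objects
(default <= 5 pixels, i.e. label fragments) are reassigned to the
surrounding majority colored class, measured by shared boundary length.
Remaining black line work is dissolved by iterative boundary absorption:
each pass, every black pixel adjacent to a colored pixel takes the
colored class with the most adjacent colored pixels (ties to the lowest
class id), which completes each line to its geodesically nearest classes.

Manual overrides and fill-from-fallback (borrowing classes from a
companion map inside listed units) round out the stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import (PROV_FALLBACK, PROV_OVERRIDE, PROV_RULE, ClassifiedMap)
from .geo import ZoneLayer
from .legend import Legend
from .segmentation import SegmentMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleanupParams:
    """black_max_channel: an object is "black" iff all three band means are
    at or below this 8-bit value.  small_object_max_px: size cutoff for the
    boundary-majority reassignment stage.  max_absorption_passes bounds the
    iterative line dissolution; leftovers become no-data with a warning."""

    black_max_channel: int = 60
    small_object_max_px: int = 5
    max_absorption_passes: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.black_max_channel <= 255:
            raise ValueError("black_max_channel must be in [0, 255]")
        if self.small_object_max_px < 1:
            raise ValueError("small_object_max_px must be >= 1")
        if self.max_absorption_passes < 1:
            raise ValueError("max_absorption_passes must be >= 1")


@dataclass(frozen=True)
class OverrideEntry:
    """One manual correction: an object id or a pixel box set to a class."""

    target_type: str  # "object" | "box"
    target: object    # int object id, or (col0, row0, col1, row1) inclusive-exclusive
    class_id: int
    reason: str = ""

    def __post_init__(self) -> None:
        if self.target_type not in ("object", "box"):
            raise ValueError(f"unknown override target type {self.target_type!r}")


@dataclass
class OverrideList:
    entries: list[OverrideEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OverrideList":
        df = pd.read_csv(path)
        entries = []
        for _, row in df.iterrows():
            tt = str(row["target_type"])
            target = (int(row["target"]) if tt == "object"
                      else tuple(int(v) for v in str(row["target"]).split(";")))
            entries.append(OverrideEntry(tt, target, int(row["class_id"]),
                                         str(row.get("reason", ""))))
        return cls(entries)


def detect_black_objects(objects: pd.DataFrame, params: CleanupParams) -> set[int]:
    """Ids of objects whose mean color is black in all three bands."""
    t = params.black_max_channel
    m = ((objects["mean_R"] <= t) & (objects["mean_G"] <= t)
         & (objects["mean_B"] <= t))
    return set(objects.index[m].astype(int).tolist())


def _label_sizes_and_adjacency(
    labels: np.ndarray,
) -> tuple[pd.Series, dict[int, dict[int, int]]]:
    """Object pixel counts and boundary-length adjacency from a label raster."""
    counts = np.bincount(labels.ravel())
    ids = np.nonzero(counts)[0]
    ids = ids[ids > 0]
    sizes = pd.Series(counts[ids], index=ids)
    adjacency: dict[int, dict[int, int]] = {int(i): {} for i in ids}
    nmax = int(labels.max(initial=0)) + 1
    pairs = []
    for sl_a, sl_b in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
    ):
        a = labels[sl_a].ravel()
        b = labels[sl_b].ravel()
        m = (a != b) & (a > 0) & (b > 0)
        if m.any():
            lo = np.minimum(a[m], b[m]).astype(np.int64)
            hi = np.maximum(a[m], b[m]).astype(np.int64)
            pairs.append(lo * nmax + hi)
    if pairs:
        keys, cnts = np.unique(np.concatenate(pairs), return_counts=True)
        for key, cnt in zip(keys.tolist(), cnts.tolist()):
            i, j = divmod(key, nmax)
            adjacency[i][j] = cnt
            adjacency[j][i] = cnt
    return sizes, adjacency


def _colored_ids(legend: Legend) -> set[int]:
    out = {c.class_id for c in legend}
    out.discard(legend.nodata_id)
    if legend.black_id is not None:
        out.discard(legend.black_id)
    return out


def absorb_black_objects(
    cmap: ClassifiedMap,
    seg: SegmentMap | None,
    params: CleanupParams,
    legend: Legend,
    black_ids: set[int] | None = None,
) -> ClassifiedMap:
    """Remove black ink from a classified map (two stages, see module doc).

    ``black_ids`` defaults to objects classified as the legend's black
    class plus objects detected black by color.  Total classified+nodata
    pixel count is conserved; afterwards no pixel carries the black class,
    and a second application is a no-op.
    """
    out = cmap.copy()
    if seg is not None:
        sizes = seg.objects["n"]
        adjacency = seg.adjacency
    else:
        sizes, adjacency = _label_sizes_and_adjacency(out.labels)
    if black_ids is None:
        if legend.black_id is not None:
            # classes, not colors: after one application nothing carries the
            # black class, so a second application is a no-op
            black_ids = set(
                out.object_classes.index[out.object_classes == legend.black_id]
                .astype(int).tolist()
            )
        else:
            black_ids = detect_black_objects(seg.objects, params)
            black_ids &= set(out.object_classes.index.tolist())
    if not black_ids:
        return out
    colored = _colored_ids(legend)

    # Stage 1: small black objects -> colored class with the longest shared
    # boundary among non-black neighbors.
    remaining: list[int] = []
    for oid in sorted(black_ids):
        n = int(sizes.get(oid, 0))
        neighbors = adjacency.get(oid, {})
        votes: dict[int, int] = {}
        for nid, blen in neighbors.items():
            if nid in black_ids:
                continue
            ncls = int(out.object_classes.get(nid, out.nodata_class))
            if ncls in colored:
                votes[ncls] = votes.get(ncls, 0) + blen
        if n <= params.small_object_max_px and votes:
            chosen = max(sorted(votes), key=lambda c: (votes[c], -c))
            out.object_classes.loc[oid] = chosen
            out.provenance.loc[oid] = PROV_RULE
            out.classes[out.labels == oid] = chosen
        else:
            remaining.append(oid)

    # Stage 2: dissolve remaining black (line) objects pixel by pixel.
    if remaining:
        black_px = np.isin(out.labels, np.asarray(remaining, dtype=np.int64))
        _absorb_pixels(out, black_px, colored, params)
        dissolved = [oid for oid in remaining
                     if not (out.labels == oid).any()]
        out.object_classes = out.object_classes.drop(index=dissolved,
                                                     errors="ignore")
        out.provenance = out.provenance.drop(index=dissolved, errors="ignore")
    return out


def _absorb_pixels(out: ClassifiedMap, black_px: np.ndarray,
                   colored: set[int], params: CleanupParams) -> None:
    """Iteratively hand black pixels to their majority colored neighbor class.

    Absorbed pixels also adopt the lowest adjacent object label of the
    winning class, keeping the pixel/object class agreement intact.
    """
    classes = out.classes
    labels = out.labels
    colored_arr = sorted(colored)
    shifts = ((-1, 0), (1, 0), (0, -1), (0, 1))

    def shifted(arr, dr, dc, fill):
        res = np.full_like(arr, fill)
        h, w = arr.shape
        res[max(0, -dr): h - max(0, dr), max(0, -dc): w - max(0, dc)] = \
            arr[max(0, dr): h - max(0, -dr) or h, max(0, dc): w - max(0, -dc) or w]
        return res

    for _ in range(params.max_absorption_passes):
        if not black_px.any():
            break
        colored_mask = ~black_px & np.isin(classes, colored_arr)
        votes = np.zeros((len(colored_arr),) + classes.shape, dtype=np.int8)
        nbr_cls = []
        nbr_lab = []
        for dr, dc in shifts:
            c = shifted(classes, dr, dc, -1)
            m = shifted(colored_mask, dr, dc, False)
            c[~m] = -1
            nbr_cls.append(c)
            lb = shifted(labels, dr, dc, 0)
            lb[~m] = 0
            nbr_lab.append(lb)
            for k, cid in enumerate(colored_arr):
                votes[k] += c == cid
        total = votes.sum(axis=0)
        absorbable = black_px & (total > 0)
        if not absorbable.any():
            break
        winner_idx = votes.argmax(axis=0)  # argmax takes the first (lowest id) on ties
        winner_cls = np.asarray(colored_arr, dtype=np.int16)[winner_idx]
        # lowest adjacent label of the winning class
        big = np.iinfo(np.int32).max
        lab_min = np.full(classes.shape, big, dtype=np.int64)
        for c, lb in zip(nbr_cls, nbr_lab):
            cand = np.where((c == winner_cls) & (lb > 0), lb, big)
            lab_min = np.minimum(lab_min, cand)
        classes[absorbable] = winner_cls[absorbable]
        labels[absorbable] = lab_min[absorbable].astype(np.int32)
        black_px &= ~absorbable
    if black_px.any():
        warnings.warn(f"{int(black_px.sum())} black pixels could not be absorbed; "
                      "set to no-data")
        classes[black_px] = out.nodata_class
        labels[black_px] = 0


def apply_overrides(
    cmap: ClassifiedMap, overrides: OverrideList, legend: Legend
) -> ClassifiedMap:
    """Apply manual corrections; later entries win on overlap; all logged."""
    out = cmap.copy()
    next_id = int(out.labels.max(initial=0)) + 1
    for entry in overrides.entries:
        if entry.class_id not in legend:
            raise ValueError(f"override class {entry.class_id} not in legend")
        if entry.target_type == "object":
            oid = int(entry.target)
            if oid not in out.object_classes.index:
                raise KeyError(f"override names unknown object id {oid}")
            out.object_classes.loc[oid] = entry.class_id
            out.provenance.loc[oid] = PROV_OVERRIDE
            out.classes[out.labels == oid] = entry.class_id
        else:
            c0, r0, c1, r1 = entry.target
            box = np.zeros(out.shape, dtype=bool)
            box[r0:r1, c0:c1] = True
            if not box.any():
                raise ValueError(f"override box {entry.target} is empty")
            out.classes[box] = entry.class_id
            out.labels[box] = next_id
            out.object_classes.loc[next_id] = entry.class_id
            out.provenance.loc[next_id] = PROV_OVERRIDE
            next_id += 1
        log.info("override applied: %s %s -> class %s (%s)",
                 entry.target_type, entry.target, entry.class_id, entry.reason)
    # drop object entries whose pixels were fully overwritten by boxes
    alive = np.unique(out.labels[out.labels > 0])
    gone = out.object_classes.index.difference(alive)
    out.object_classes = out.object_classes.drop(index=gone, errors="ignore")
    out.provenance = out.provenance.drop(index=gone, errors="ignore")
    return out


def fill_missing_from(
    primary: ClassifiedMap,
    fallback: ClassifiedMap,
    zones: ZoneLayer,
    unit_ids: Sequence[str],
    legend: Legend,
) -> ClassifiedMap:
    """Borrow classes from a companion map inside listed units.

    Within each listed unit, pixels that are no-data in the primary map
    take the fallback map's class (provenance: fallback-map).  Both maps
    must share the exact grid.
    """
    if primary.shape != fallback.shape or primary.transform != fallback.transform:
        raise ValueError("primary and fallback maps are not on the same grid")
    out = primary.copy()
    if not unit_ids:
        return out
    unknown = [u for u in unit_ids if u not in zones.unit_ids]
    if unknown:
        raise KeyError(f"unit ids not in zone layer: {unknown}")
    from .zonal import rasterize_zones

    unit_raster = rasterize_zones(zones, primary.transform, primary.shape)
    idx = {u: i for i, u in enumerate(zones.unit_ids)}
    sel = np.isin(unit_raster, [idx[u] for u in unit_ids])
    fillable = sel & (out.classes == out.nodata_class) \
        & (fallback.classes != fallback.nodata_class)
    if not fillable.any():
        return out
    offset = int(max(out.labels.max(initial=0),
                     out.object_classes.index.max() if len(out.object_classes) else 0))
    out.classes[fillable] = fallback.classes[fillable]
    new_labels = fallback.labels[fillable].astype(np.int64) + offset
    out.labels[fillable] = new_labels.astype(np.int32)
    for oid in np.unique(new_labels):
        src = int(oid - offset)
        out.object_classes.loc[int(oid)] = int(fallback.object_classes.get(
            src, fallback.nodata_class))
        out.provenance.loc[int(oid)] = PROV_FALLBACK
    return out
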