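"""Synthetic choropleth maps with known ground truth.

Emulates the kind of scanned thematic map the pipeline digitizes: a
Voronoi tessellation of units, each filled with its class's legend color,
black unit borders and small black "label" glyph blocks, then degraded by
Gaussian blur and additive noise (published scans have poor resolution
and color-mixed borders).  The generator records per-pixel ground truth —
border and glyph pixels carry their underlying unit's class — so recovery
by any backend can be scored exactly.  All stochastic steps are driven by
a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import binary_dilation, gaussian_filter
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .classify import ClassifiedMap, TrainingSet
from .geo import Affine, RasterImage, ZoneLayer
from .legend import Legend, deer_density_legend
from .segmentation import SegmentMap
from .zonal import ZonalTable, rasterize_zones


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Study conditions for a synthetic map.

    Defaults model a small published national map scan: 600×400 pixels at
    1 km/pixel, 30 units, the four-class deer density legend, mild spatial
    coherence, 1-pixel black borders, a couple of label glyphs per unit,
    and light degradation (blur σ 0.5 px, noise SD 4 8-bit units).
    """

    n_units: int = 30
    width: int = 600
    height: int = 400
    resolution: float = 1000.0  # m per pixel
    legend: Legend = field(default_factory=deer_density_legend)
    class_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    smoothing_iters: int = 1
    border_width: int = 1
    label_density: float = 2.0  # expected glyph blocks per unit
    blur_sigma: float = 0.5
    noise_sd: float = 4.0
    seed: int = 0
    crs: str = "EPSG:5070"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if len(self.class_probs) != len(self.legend.density_ids):
            raise ValueError("one probability per density class required")
        if self.border_width < 0:
            raise ValueError("border_width must be >= 0")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("degradation parameters must be >= 0")

    @property
    def transform(self) -> Affine:
        return Affine.from_origin(0.0, self.height * self.resolution,
                                  self.resolution, self.resolution)

    @property
    def extent(self):
        return box(0.0, 0.0, self.width * self.resolution,
                   self.height * self.resolution)


@dataclass
class GroundTruth:
    """Per-pixel truth for a rendered synthetic map.

    ``classes``: the underlying density class of every pixel (border and
    glyph pixels carry their unit's class).  ``rendered``: what was
    actually painted (class ids, with the legend's black id on ink
    pixels) — the layer a human labeling training objects would see.
    ``unit_raster``: unit index per pixel.  ``unit_classes``: class per
    unit id.
    """

    classes: np.ndarray
    rendered: np.ndarray
    unit_raster: np.ndarray
    unit_classes: pd.Series
    zones: ZoneLayer
    transform: Affine
    crs: str

    @property
    def ink_mask(self) -> np.ndarray:
        return self.classes != self.rendered


def generate_tessellation(spec: SyntheticMapSpec) -> ZoneLayer:
    """Voronoi cells of n_units uniform random points, clipped to the extent.

    Deterministic per seed.  Units are grouped into pseudo-states by seed
    x-coordinate quartile so state-level aggregation is exercised too.
    """
    rng = np.random.default_rng(spec.seed)
    ext = spec.extent
    minx, miny, maxx, maxy = ext.bounds
    pts = rng.uniform((minx, miny), (maxx, maxy), size=(spec.n_units, 2))
    # re-jitter exact duplicates (vanishingly rare with float draws)
    for _ in range(10):
        _, idx, cnt = np.unique(pts.round(6), axis=0, return_index=True,
                                return_counts=True)
        if (cnt == 1).all():
            break
        dupes = np.setdiff1d(np.arange(len(pts)), idx)
        pts[dupes] += rng.uniform(-1, 1, (len(dupes), 2))

    if spec.n_units == 1:
        cells = [ext]
    else:
        diagram = voronoi_diagram(MultiPoint(pts), envelope=ext)
        cells_raw = list(diagram.geoms)
        cells = [None] * spec.n_units
        tree = shapely.STRtree(cells_raw)
        for i, p in enumerate(pts):
            j = tree.query(Point(p), predicate="within")
            cells[i] = cells_raw[int(j[0])].intersection(ext)

    quart = np.searchsorted(np.quantile(pts[:, 0], [0.25, 0.5, 0.75]), pts[:, 0])
    rows = [{
        "unit_id": f"U{i:03d}",
        "state_id": f"S{int(quart[i]) + 1}",
        "geometry": cells[i],
        "official_area_km2": cells[i].area / 1e6,
    } for i in range(spec.n_units)]
    return ZoneLayer(pd.DataFrame(rows), crs=spec.crs)


def _unit_adjacency(zones: ZoneLayer) -> dict[int, list[int]]:
    geoms = list(zones.units["geometry"])
    tree = shapely.STRtree(geoms)
    adj: dict[int, list[int]] = {i: [] for i in range(len(geoms))}
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j != i and geoms[i].intersection(geoms[j]).length > 0:
                adj[i].append(j)
    return adj


def assign_unit_classes(zones: ZoneLayer, spec: SyntheticMapSpec) -> pd.Series:
    """Draw unit classes iid from class_probs, then apply neighbor-majority
    smoothing passes for spatial coherence (ties keep the current class)."""
    rng = np.random.default_rng(spec.seed + 1)
    ids = spec.legend.density_ids
    cls = rng.choice(ids, size=len(zones), p=spec.class_probs)
    adj = _unit_adjacency(zones)
    for _ in range(spec.smoothing_iters):
        new = cls.copy()
        for i in range(len(zones)):
            votes = pd.Series([cls[j] for j in adj[i]] + [cls[i]]).value_counts()
            top = votes.max()
            winners = sorted(votes[votes == top].index)
            new[i] = cls[i] if cls[i] in winners else winners[0]
        cls = new
    return pd.Series(cls, index=zones.unit_ids, name="class_id")


def render_choropleth(
    zones: ZoneLayer, classes: pd.Series, spec: SyntheticMapSpec
) -> tuple[RasterImage, GroundTruth]:
    """Paint the tessellation: legend fill colors, black borders and glyphs."""
    h, w = spec.height, spec.width
    if spec.border_width > min(h, w) // 4:
        raise ValueError("resolution too coarse to render borders")
    transform = spec.transform
    unit_raster = rasterize_zones(zones, transform, (h, w))
    if (unit_raster < 0).any():
        # centers exactly on cell edges: assign to nearest seed centroid
        missing = np.argwhere(unit_raster < 0)
        cents = np.array([[g.centroid.x, g.centroid.y]
                          for g in zones.units["geometry"]])
        X, Y = transform.pixel_centers(w, h)
        for r, c in missing:
            d = (cents[:, 0] - X[r, c]) ** 2 + (cents[:, 1] - Y[r, c]) ** 2
            unit_raster[r, c] = int(d.argmin())

    cls_per_unit = classes.reindex(zones.unit_ids).to_numpy(int)
    truth = cls_per_unit[unit_raster].astype(np.int16)

    rendered = truth.copy()
    black_id = spec.legend.black_id
    if black_id is None:
        raise ValueError("legend must define a black ink class to render borders")
    if spec.border_width > 0:
        edge = np.zeros((h, w), bool)
        edge[:, :-1] |= unit_raster[:, :-1] != unit_raster[:, 1:]
        edge[:-1, :] |= unit_raster[:-1, :] != unit_raster[1:, :]
        if spec.border_width > 1:
            edge = binary_dilation(edge, iterations=spec.border_width - 1)
        rendered[edge] = black_id

    rng = np.random.default_rng(spec.seed + 2)
    for i in range(len(zones)):
        n_glyphs = rng.poisson(spec.label_density)
        rows_i, cols_i = np.nonzero(unit_raster == i)
        if rows_i.size == 0:
            continue
        for _ in range(n_glyphs):
            k = rng.integers(0, rows_i.size)
            gh = int(rng.integers(2, 4))
            gw = int(rng.integers(2, 5))
            r0, c0 = int(rows_i[k]), int(cols_i[k])
            rendered[r0:r0 + gh, c0:c0 + gw] = black_id

    colors = spec.legend.colors()
    palette = np.zeros((max(colors) + 1, 3), dtype=np.uint8)
    for cid, col in colors.items():
        palette[cid] = col
    pixels = palette[rendered]
    img = RasterImage(pixels, transform, spec.crs)
    gt = GroundTruth(truth, rendered, unit_raster,
                     pd.Series(cls_per_unit, index=zones.unit_ids),
                     zones, transform, spec.crs)
    return img, gt


def degrade(img: RasterImage, spec: SyntheticMapSpec) -> RasterImage:
    """Gaussian blur then additive Gaussian noise, clipped to [0, 255]."""
    arr = img.pixels.astype(np.float64)
    if spec.blur_sigma > 0:
        arr = np.stack([gaussian_filter(arr[..., b], spec.blur_sigma)
                        for b in range(3)], axis=-1)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 3)
        arr = arr + rng.normal(0.0, spec.noise_sd, arr.shape)
    out = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return RasterImage(out, img.transform, img.crs, img.valid_mask)


def make_synthetic_map(
    spec: SyntheticMapSpec,
) -> tuple[RasterImage, GroundTruth, ZoneLayer]:
    """Full generator: tessellate, assign classes, render, degrade."""
    zones = generate_tessellation(spec)
    classes = assign_unit_classes(zones, spec)
    clean, gt = render_choropleth(zones, classes, spec)
    return degrade(clean, spec), gt, zones


def sample_training_set(
    seg: SegmentMap, gt: GroundTruth, fraction: float = 0.1, seed: int = 0
) -> TrainingSet:
    """Label a random sample of image objects from the rendered truth.

    Stands in for an analyst hand-labeling objects by their visible color:
    each sampled object gets the majority *rendered* category of its
    pixels (a density class, or the black ink class).  Any rendered
    category missed by the sample is topped up with its largest object so
    every class has at least one example.
    """
    labels = seg.labels
    rendered = gt.rendered.astype(np.int64)
    nmax = int(labels.max()) + 1
    k = int(rendered.max()) + 1
    valid = labels > 0
    enc = labels[valid].astype(np.int64) * k + rendered[valid]
    counts = np.bincount(enc, minlength=nmax * k).reshape(nmax, k)
    majority = counts.argmax(axis=1)
    obj_ids = seg.objects.index.to_numpy()
    obj_label = pd.Series(majority[obj_ids], index=obj_ids)

    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * len(obj_ids))))
    chosen = rng.choice(obj_ids, size=n, replace=False)
    picked = obj_label.loc[chosen]
    for cat in np.unique(obj_label):
        if cat not in picked.values:
            pool = obj_label.index[obj_label == cat]
            sizes = seg.objects.loc[pool, "n"]
            picked.loc[int(sizes.idxmax())] = cat
    return TrainingSet(picked)


@dataclass
class RecoveryReport:
    """Scores of a digitization run against ground truth."""

    confusion: pd.DataFrame  # rows: truth class, cols: mapped class
    pixel_accuracy: float
    unit_majority_accuracy: float
    producer_accuracy: pd.Series
    user_accuracy: pd.Series


def evaluate_recovery(
    gt: GroundTruth, cmap: ClassifiedMap, zt: ZonalTable | None = None
) -> RecoveryReport:
    """Confusion matrix and accuracies of a classified map vs ground truth."""
    if cmap.shape != gt.classes.shape:
        raise ValueError("classified map and truth are not on the same grid")
    truth = gt.classes.astype(np.int64).ravel()
    mapped = cmap.classes.astype(np.int64).ravel()
    ids = np.unique(np.concatenate([truth, mapped]))
    lut = {int(v): i for i, v in enumerate(ids)}
    k = len(ids)
    enc = np.vectorize(lut.get)(truth) * k + np.vectorize(lut.get)(mapped)
    cm = np.bincount(enc, minlength=k * k).reshape(k, k)
    confusion = pd.DataFrame(cm, index=pd.Index(ids, name="truth"),
                             columns=pd.Index(ids, name="mapped"))
    pixel_acc = float(np.trace(cm) / cm.sum())

    # per-unit majority of the mapped classes vs the unit's true class
    n_units = int(gt.unit_raster.max()) + 1
    correct = 0
    for i in range(n_units):
        m = gt.unit_raster == i
        vals, cnts = np.unique(cmap.classes[m], return_counts=True)
        if vals.size and int(vals[cnts.argmax()]) == int(gt.unit_classes.iloc[i]):
            correct += 1
    unit_acc = correct / n_units

    with np.errstate(divide="ignore", invalid="ignore"):
        producer = pd.Series(np.diag(cm) / cm.sum(axis=1), index=ids)
        user = pd.Series(np.diag(cm) / cm.sum(axis=0), index=ids)
    return RecoveryReport(confusion, pixel_acc, unit_acc, producer, user)
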