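"""Object-based image analysis: multiresolution region-merging segmentation.

The map image is partitioned bottom-up into homogeneous "image objects".
Every valid pixel starts as its own object; adjacent objects merge while
the color-heterogeneity increase of the merge stays below the squared
scale parameter.  The heterogeneity of an object is ``n·σ_b`` summed over
bands with user weights, so the cost of merging A and B is

    Δh = Σ_b w_b · [ n_AB·σ_b(A∪B) − (n_A·σ_b(A) + n_B·σ_b(B)) ]  ≥ 0

with population standard deviations.  A merge executes only under *mutual
best fit*: each object must be the other's minimum-cost neighbor.  Passes
over all objects repeat until a pass makes no merge.  Iteration order is
deterministic (ascending object id; cost ties broken by the lower neighbor
id; the merged object keeps the smaller id), so a segmentation is exactly
reproducible.

A small scale parameter keeps mixed-color boundary objects from forming on
low-resolution scans whose class borders blur into intermediate colors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping

import numpy as np
import pandas as pd

from .geo import Affine, RasterImage

__all__ = [
    "SegmentationParams",
    "SegmentMap",
    "MultiresolutionSegmenter",
    "multiresolution_segment",
    "compute_object_stats",
]

OBJECT_COLUMNS = ["n", "mean_R", "mean_G", "mean_B", "sd_R", "sd_G", "sd_B"]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the region-merging segmentation.

    scale : merge threshold; a merge needs cost < scale².  Unitless, in
        8-bit color units; default 10 suits flat-palette choropleth scans.
    band_weights : relative weight of the R, G, B bands in the cost.
    connectivity : 4 or 8 pixel neighborhood (4 keeps thin black border
        lines from leaking classes diagonally).
    """

    scale: float = 10.0
    band_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if len(self.band_weights) != 3 or any(w < 0 for w in self.band_weights):
            raise ValueError("band_weights must be 3 nonnegative values")
        if sum(self.band_weights) <= 0:
            raise ValueError("at least one band weight must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class SegmentMap:
    """A partition of the image into objects.

    ``labels`` holds a per-pixel object id >= 1 (0 = nodata).  ``objects``
    is a DataFrame indexed by id with pixel count and per-band color mean
    and population SD.  ``adjacency`` maps id -> {neighbor id: shared
    boundary length in pixel edges} and is symmetric.
    """

    labels: np.ndarray
    objects: pd.DataFrame
    adjacency: dict[int, dict[int, int]]
    transform: Affine = field(default_factory=Affine.identity)
    crs: str = ""

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int]]:
    offs = [(0, 1), (1, 0)]
    if connectivity == 8:
        offs += [(1, 1), (1, -1)]
    return offs


def compute_object_stats(
    pixels: np.ndarray, labels: np.ndarray
) -> tuple[pd.DataFrame, dict[int, dict[int, int]]]:
    """Per-object pixel counts, color means/SDs and boundary-length adjacency.

    Single vectorized pass; results are independent of pixel order.  Label
    0 is nodata and excluded.  Boundary lengths count shared 4-neighbor
    pixel edges.
    """
    pixels = np.asarray(pixels)
    labels = np.asarray(labels)
    if pixels.shape[:2] != labels.shape:
        raise ValueError(
            f"label grid {labels.shape} does not match raster {pixels.shape[:2]}"
        )
    flat = labels.ravel()
    valid = flat > 0
    lab = flat[valid]
    nmax = int(labels.max(initial=0)) + 1
    counts = np.bincount(lab, minlength=nmax)
    ids = np.nonzero(counts)[0]

    data = {"n": counts[ids]}
    for bi, bname in enumerate("RGB"):
        v = pixels[..., bi].ravel()[valid].astype(np.float64)
        s = np.bincount(lab, weights=v, minlength=nmax)
        ss = np.bincount(lab, weights=v * v, minlength=nmax)
        mean = s[ids] / counts[ids]
        var = np.maximum(ss[ids] / counts[ids] - mean**2, 0.0)
        data[f"mean_{bname}"] = mean
        data[f"sd_{bname}"] = np.sqrt(var)
    objects = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    objects = objects[OBJECT_COLUMNS]

    adjacency: dict[int, dict[int, int]] = {int(i): {} for i in ids}
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
    return objects, adjacency


def _prepare_pixels(img) -> tuple[np.ndarray, np.ndarray, Affine, str]:
    if isinstance(img, RasterImage):
        return img.pixels, img.mask(), img.transform, img.crs
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (h, w, 3) image, got {arr.shape}")
    return arr, np.ones(arr.shape[:2], bool), Affine.identity(), ""


def multiresolution_segment(img, params: SegmentationParams | None = None) -> SegmentMap:
    """Segment a 3-band image by mutual-best-fit region merging.

    Accepts a :class:`RasterImage` or a plain (h, w, 3) array.  See the
    module docstring for the merge rule.  Nodata pixels get label 0 and
    belong to no object.
    """
    params = params or SegmentationParams()
    pixels, mask, transform, crs = _prepare_pixels(img)
    h, w = pixels.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    if not mask.any():
        raise ValueError("image is entirely nodata")

    # pixel -> initial object index (0..K-1 over valid pixels, row-major)
    idx = np.full((h, w), -1, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    K = int(mask.sum())

    wr, wg, wb = (float(x) for x in params.band_weights)
    pr = pixels[..., 0].astype(np.float64)[mask]
    pg = pixels[..., 1].astype(np.float64)[mask]
    pb = pixels[..., 2].astype(np.float64)[mask]

    cnt = [1.0] * K
    sr, sg, sb = pr.tolist(), pg.tolist(), pb.tolist()
    ssr = (pr * pr).tolist()
    ssg = (pg * pg).tolist()
    ssb = (pb * pb).tolist()
    het = [0.0] * K  # cached Σ_b w_b · n·σ_b per object (0 for single pixels)

    nbr: list[dict[int, int] | None] = [dict() for _ in range(K)]
    for dr, dc in _neighbor_offsets(params.connectivity):
        a = idx[0: h - dr, max(0, -dc): w - max(0, dc)]
        b = idx[dr: h, max(0, dc): w - max(0, -dc) or w]
        m = (a >= 0) & (b >= 0)
        for i, j in zip(a[m].tolist(), b[m].tolist()):
            nbr[i][j] = nbr[i].get(j, 0) + 1
            nbr[j][i] = nbr[j].get(i, 0) + 1

    parent = list(range(K))
    alive = [True] * K
    threshold = params.scale * params.scale

    def merge(m: int, o: int) -> None:
        cnt[m] += cnt[o]
        sr[m] += sr[o]; sg[m] += sg[o]; sb[m] += sb[o]
        ssr[m] += ssr[o]; ssg[m] += ssg[o]; ssb[m] += ssb[o]
        n = cnt[m]
        hm = 0.0
        for wgt, s, ss in ((wr, sr, ssr), (wg, sg, ssg), (wb, sb, ssb)):
            mu = s[m] / n
            var = ss[m] / n - mu * mu
            if var > 0:
                hm += wgt * n * sqrt(var)
        het[m] = hm
        dm = nbr[m]
        dm.pop(o, None)
        for k, blen in nbr[o].items():
            if k == m:
                continue
            dk = nbr[k]
            dk.pop(o, None)
            dm[k] = dm.get(k, 0) + blen
            dk[m] = dm[k]
        nbr[o] = None
        alive[o] = False
        parent[o] = m

    def best_neighbor(i: int) -> tuple[int, float]:
        ni = cnt[i]
        sri, sgi, sbi = sr[i], sg[i], sb[i]
        ssri, ssgi, ssbi = ssr[i], ssg[i], ssb[i]
        hi = het[i]
        bj, bc = -1, float("inf")
        for j in nbr[i]:
            n = ni + cnt[j]
            c = -hi - het[j]
            su = sri + sr[j]; mu = su / n
            var = (ssri + ssr[j]) / n - mu * mu
            if var > 0:
                c += wr * n * sqrt(var)
            su = sgi + sg[j]; mu = su / n
            var = (ssgi + ssg[j]) / n - mu * mu
            if var > 0:
                c += wg * n * sqrt(var)
            su = sbi + sb[j]; mu = su / n
            var = (ssbi + ssb[j]) / n - mu * mu
            if var > 0:
                c += wb * n * sqrt(var)
            if c < bc or (c == bc and j < bj):
                bj, bc = j, c
        return bj, bc

    changed = True
    while changed:
        changed = False
        for i in range(K):
            if not alive[i] or not nbr[i]:
                continue
            j, cij = best_neighbor(i)
            if j < 0 or cij >= threshold:
                continue
            j2, _ = best_neighbor(j)
            if j2 != i:
                continue
            if i < j:
                merge(i, j)
            else:
                merge(j, i)
            changed = True

    # resolve union-find chains, relabel contiguously (ascending surviving id)
    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    roots = sorted({find(x) for x in range(K)})
    new_id = {r: i + 1 for i, r in enumerate(roots)}
    flat_final = np.fromiter((new_id[find(x)] for x in range(K)), dtype=np.int32,
                             count=K)
    labels = np.zeros((h, w), dtype=np.int32)
    labels[mask] = flat_final

    objects, adjacency = compute_object_stats(pixels, labels)
    return SegmentMap(labels, objects, adjacency, transform, crs)


class MultiresolutionSegmenter:
    """Estimator-style front end for the region-merging segmentation.

    ``transform(image)`` returns a :class:`SegmentMap`.  Stateless apart
    from its parameters; ``fit`` is a no-op kept for pipeline
    compatibility.
    """

    def __init__(self, scale: float = 10.0,
                 band_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 connectivity: int = 4):
        self.scale = scale
        self.band_weights = band_weights
        self.connectivity = connectivity

    def get_params(self, deep: bool = True) -> dict:
        return {"scale": self.scale, "band_weights": self.band_weights,
                "connectivity": self.connectivity}

    def set_params(self, **params) -> "MultiresolutionSegmenter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "MultiresolutionSegmenter":
        return self

    def transform(self, image) -> SegmentMap:
        return multiresolution_segment(image, self._params())

    segment = transform

    def _params(self) -> SegmentationParams:
        return SegmentationParams(self.scale, tuple(self.band_weights),
                                  self.connectivity)
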