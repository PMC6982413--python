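"""Slow reference implementation of the region-merging segmentation.

Used to validate the incremental pass-based implementation in
:mod:`chorodig.segmentation`: this version keeps no running state — at
every visit it recomputes every object's statistics and the adjacency
relation from scratch from the label raster and the image, then evaluates
the candidate merge costs.  Only suitable for small images.

The merge semantics are the stated ones: visit alive objects in ascending
id; an object merges with its minimum-cost neighbor (ties to the lower
id) iff the cost is below scale² and the choice is mutual; the merged
object keeps the smaller id; passes repeat until none merges.

Population standard deviations are computed from integer sums and sums of
squares, which are order-exact in float64, so costs here are bit-identical
to the incremental implementation's and tie-breaking agrees exactly.
"""

from __future__ import annotations

from math import sqrt

import numpy as np


def _recompute(pixels: np.ndarray, labels: np.ndarray, weights, K: int):
    """All object stats (n, per-band sums/sumsq, heterogeneity) + adjacency,
    recomputed from scratch.  K is one past the highest initial object id."""
    flat = labels.ravel()
    valid = flat > 0
    lab = flat[valid]
    n = np.bincount(lab, minlength=K).astype(np.float64)
    het = np.zeros(K)
    sums = []
    ssums = []
    for b in range(3):
        v = pixels[..., b].ravel()[valid].astype(np.float64)
        s = np.bincount(lab, weights=v, minlength=K)
        ss = np.bincount(lab, weights=v * v, minlength=K)
        sums.append(s)
        ssums.append(ss)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = s / n
            var = ss / n - mu * mu
        var = np.where(np.isfinite(var), var, 0.0)
        het = het + np.where(var > 0, weights[b] * n * np.sqrt(np.maximum(var, 0)), 0.0)
    n = n.tolist()
    sums = [s.tolist() for s in sums]
    ssums = [ss.tolist() for ss in ssums]
    het = het.tolist()

    adj: dict[int, set[int]] = {}
    for sl_a, sl_b in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
    ):
        a = labels[sl_a].ravel()
        b = labels[sl_b].ravel()
        m = (a != b) & (a > 0) & (b > 0)
        for i, j in zip(a[m].tolist(), b[m].tolist()):
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
    return n, sums, ssums, het, adj


def _best(i: int, n, sums, ssums, het, adj, weights) -> tuple[int, float]:
    """Minimum-cost neighbor of object i (ties to the lower id)."""
    bj, bc = -1, float("inf")
    for j in sorted(adj.get(i, ())):
        nu = n[i] + n[j]
        c = -het[i] - het[j]
        for b in range(3):
            su = sums[b][i] + sums[b][j]
            mu = su / nu
            var = (ssums[b][i] + ssums[b][j]) / nu - mu * mu
            if var > 0:
                c += weights[b] * nu * sqrt(var)
        if c < bc:
            bj, bc = j, c
    return bj, bc


def multiresolution_segment_reference(
    pixels: np.ndarray,
    scale: float,
    band_weights=(1.0, 1.0, 1.0),
    connectivity: int = 4,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Label raster of the reference segmentation (0 = nodata)."""
    if connectivity != 4:
        raise NotImplementedError("reference supports 4-connectivity only")
    pixels = np.asarray(pixels)
    h, w = pixels.shape[:2]
    if mask is None:
        mask = np.ones((h, w), bool)
    labels = np.zeros((h, w), dtype=np.int64)
    labels[mask] = np.arange(1, int(mask.sum()) + 1)
    threshold = scale * scale
    K = int(labels.max())

    changed = True
    while changed:
        changed = False
        # stats only change at merges, so recomputing from the raster after
        # every merge is identical to recomputing at every visit
        n, sums, ssums, het, adj = _recompute(pixels, labels, band_weights, K + 1)
        for i in range(1, K + 1):
            if n[i] == 0:
                continue
            j, cij = _best(i, n, sums, ssums, het, adj, band_weights)
            if j >= 0 and cij < threshold:
                j2, _ = _best(j, n, sums, ssums, het, adj, band_weights)
                if j2 == i:
                    m, o = (i, j) if i < j else (j, i)
                    labels[labels == o] = m
                    changed = True
                    n, sums, ssums, het, adj = _recompute(pixels, labels,
                                                          band_weights, K + 1)

    survivors = np.unique(labels[labels > 0])
    remap = {int(s): k + 1 for k, s in enumerate(survivors)}
    out = np.zeros_like(labels, dtype=np.int32)
    for s, k in remap.items():
        out[labels == s] = k
    return out
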