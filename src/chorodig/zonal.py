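"""Zonal summaries: class areas per unit, majority classes, change analysis.

The classified raster is intersected with a polygon unit layer (counties)
by the pixel-center rule: a pixel belongs to the unit containing its
center.  Class areas are pixel counts times pixel area, percentages are
relative to the unit's official area, and a unit's majority class is
accepted only when it beats the runner-up by more than a margin (default
25 percentage points) and when enough of the unit carries any density
class at all (default 25%) — guards against mixed and partially mapped
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .classify import ClassifiedMap
from .geo import Affine, ZoneLayer
from .legend import Legend

AREA_TOLERANCE = 0.05  # relative slack on sum(class areas) vs official area


@dataclass(frozen=True)
class ZonalParams:
    """majority_margin: percentage points the top class must beat the
    second by (strict) for a unit to count as having a clear majority.
    min_coverage: minimum fraction of the official unit area carrying any
    density class."""

    majority_margin: float = 25.0
    min_coverage: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.majority_margin <= 100:
            raise ValueError("majority_margin must be in [0, 100]")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")


@dataclass
class ZonalTable:
    """Per-unit class areas plus unit-level majority diagnostics.

    ``table``: one row per (unit, class) with area_km2 and percent of the
    official unit area.  ``units``: one row per unit with coverage (density
    class fraction), majority class, margin (pct points between top and
    second density class) and validity.  Majority columns are NaN until
    :func:`assign_majority` runs.
    """

    table: pd.DataFrame
    units: pd.DataFrame
    legend: Legend

    def state_class_areas(self) -> pd.DataFrame:
        """Class areas (km2) aggregated to states."""
        t = self.table.merge(self.units[["unit_id", "state_id"]], on="unit_id")
        return (t.groupby(["state_id", "class_id"])["area_km2"].sum()
                .reset_index())

    def national_class_areas(self) -> pd.Series:
        return self.table.groupby("class_id")["area_km2"].sum()

    def to_csv(self, path: str | Path) -> None:
        merged = self.table.merge(
            self.units[["unit_id", "state_id", "coverage", "majority",
                        "margin", "valid"]],
            on="unit_id",
        )
        merged.to_csv(path, index=False)


def rasterize_zones(zones: ZoneLayer, transform: Affine,
                    shape: tuple[int, int]) -> np.ndarray:
    """Unit-index raster by the pixel-center rule (-1 where no unit).

    Ties on shared boundaries are impossible for valid tessellations
    except for centers exactly on an edge; the first unit in layer order
    wins there.
    """
    h, w = shape
    X, Y = transform.pixel_centers(w, h)
    out = np.full((h, w), -1, dtype=np.int32)
    inv = transform.invert()
    for i, geom in enumerate(zones.units["geometry"]):
        minx, miny, maxx, maxy = geom.bounds
        corners_c, corners_r = inv.apply([minx, maxx, minx, maxx],
                                         [miny, miny, maxy, maxy])
        c0 = max(0, int(np.floor(corners_c.min())) - 1)
        c1 = min(w, int(np.ceil(corners_c.max())) + 1)
        r0 = max(0, int(np.floor(corners_r.min())) - 1)
        r1 = min(h, int(np.ceil(corners_r.max())) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        sub = out[r0:r1, c0:c1]
        unassigned = sub < 0
        if not unassigned.any():
            continue
        xs = X[r0:r1, c0:c1][unassigned]
        ys = Y[r0:r1, c0:c1][unassigned]
        inside = shapely.contains_xy(geom, xs, ys)
        vals = sub[unassigned]
        vals[inside] = i
        sub[unassigned] = vals
    return out


def zonal_class_areas(
    cmap: ClassifiedMap, zones: ZoneLayer, legend: Legend
) -> ZonalTable:
    """Class area and percent of official area per unit (pixel-center rule)."""
    if cmap.crs and zones.crs and cmap.crs != zones.crs:
        raise ValueError(f"CRS mismatch: raster {cmap.crs!r} vs zones {zones.crs!r}")
    h, w = cmap.shape
    unit_raster = rasterize_zones(zones, cmap.transform, (h, w))
    px_km2 = cmap.transform.pixel_area / 1e6

    class_ids = legend.class_ids
    cls_index = {c: k for k, c in enumerate(class_ids)}
    n_units = len(zones)
    inside = unit_raster >= 0
    u = unit_raster[inside].astype(np.int64)
    c = cmap.classes[inside].astype(np.int64)
    # map class values to compact indices
    lut = np.full(int(c.max(initial=0)) + 1, -1, dtype=np.int64)
    for v, k in cls_index.items():
        if 0 <= v < lut.size:
            lut[v] = k
    ci = lut[c] if c.size else c
    keep = ci >= 0
    enc = u[keep] * len(class_ids) + ci[keep]
    counts = np.bincount(enc, minlength=n_units * len(class_ids))
    counts = counts.reshape(n_units, len(class_ids))

    rows = []
    density = set(legend.density_ids)
    units_rows = []
    for i in range(n_units):
        unit = zones.units.iloc[i]
        official = float(unit.official_area_km2)
        dens_area = 0.0
        for k, cid in enumerate(class_ids):
            area = counts[i, k] * px_km2
            if cid in density:
                dens_area += area
            rows.append({
                "unit_id": unit.unit_id, "class_id": cid,
                "area_km2": area, "percent": 100.0 * area / official,
            })
        units_rows.append({
            "unit_id": unit.unit_id, "state_id": unit.state_id,
            "official_area_km2": official,
            "coverage": dens_area / official,
            "majority": np.nan, "margin": np.nan, "valid": np.nan,
        })
    table = pd.DataFrame(rows)
    units = pd.DataFrame(units_rows)
    return ZonalTable(table, units, legend)


def assign_majority(zt: ZonalTable, params: ZonalParams | None = None) -> ZonalTable:
    """Majority density class per unit with the clear-majority margin rule.

    majority = density class with the greatest percent area; margin = its
    percent minus the runner-up's; valid requires margin strictly above
    ``majority_margin`` *and* coverage at least ``min_coverage``.  Only
    density classes compete — no-data and ink never hold a majority.
    """
    params = params or ZonalParams()
    density = zt.legend.density_ids
    t = zt.table[zt.table.class_id.isin(density)]
    units = zt.units.copy()
    majority, margin_col, valid_col = [], [], []
    for i, unit_id in enumerate(units["unit_id"]):
        sub = t[t.unit_id == unit_id]
        if sub.empty or (sub.percent <= 0).all():
            majority.append(np.nan)
            margin_col.append(np.nan)
            valid_col.append(False)
            continue
        s = sub.sort_values(["percent", "class_id"], ascending=[False, True])
        top = s.iloc[0]
        second_pct = float(s.iloc[1].percent) if len(s) > 1 else 0.0
        margin = float(top.percent) - second_pct
        cov = float(units.iloc[i].coverage)
        majority.append(float(top.class_id))
        margin_col.append(margin)
        valid_col.append((cov >= params.min_coverage)
                         and (margin > params.majority_margin))
    units["majority"] = majority
    units["margin"] = margin_col
    units["valid"] = pd.Series(valid_col, index=units.index, dtype=bool)
    return ZonalTable(zt.table, units, zt.legend)


CHANGE_CATEGORIES = ("decreased", "same", "+1", ">+1")


def change_classes(a: ZonalTable, b: ZonalTable, legend: Legend) -> pd.DataFrame:
    """Per-unit change category between two majority-assigned tables.

    Only units valid in both tables get a category; the rest are reported
    with ``valid_both = False`` and a missing category.  Categories follow
    the ordered density-class index difference (b minus a): decreased,
    same, +1, or >+1.
    """
    ua = a.units.set_index("unit_id")
    ub = b.units.set_index("unit_id")
    if set(ua.index) != set(ub.index):
        only_a = sorted(set(ua.index) - set(ub.index))
        only_b = sorted(set(ub.index) - set(ua.index))
        raise ValueError(f"unit id mismatch; only in first: {only_a[:10]}, "
                         f"only in second: {only_b[:10]}")
    if ua["valid"].isna().any() or ub["valid"].isna().any():
        raise ValueError("both tables must be majority-assigned first")
    rows = []
    for uid in ua.index:
        ra, rb = ua.loc[uid], ub.loc[uid]
        both = bool(ra.valid) and bool(rb.valid)
        cat = None
        if both:
            d = legend.class_index(int(rb.majority)) - \
                legend.class_index(int(ra.majority))
            cat = ("decreased" if d < 0 else "same" if d == 0
                   else "+1" if d == 1 else ">+1")
        rows.append({"unit_id": uid, "majority_a": ra.majority,
                     "majority_b": rb.majority, "valid_both": both,
                     "category": cat})
    return pd.DataFrame(rows)
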