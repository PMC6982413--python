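"""Populations and densities from class areas, calibration, and comparisons.

Class areas become populations linearly: P = Σ_c A_c · v_c over presence
classes, where v_c is the density value (animals/km²) the legend attaches
to class c.  For an open-ended low class whose representative value is
unknown, the value is calibrated so the national population matches an
externally known total (for the 2003 white-tailed deer map, ~30 million
animals gives 1.85 deer/km² for the <5.8 class, the upper classes keeping
their interval lower bounds 5.8/11.6/17.4).

Comparison utilities reproduce the agency-versus-map error statistics:
signed differences (reported − map), quotients, totals, mean absolute
error, and multi-year means with sample (n−1) standard deviations.

Bundled reference tables (state populations/densities/presence areas for
the digitized 1982 and 2003 national deer density maps, QDMA 2005 state
estimates, and Southeast Deer Study Group 2001–2005 annual estimates) are
exposed through ``load_*`` helpers for regression and comparison work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import ZoneLayer
from .legend import Legend
from .zonal import ZonalTable


@dataclass(frozen=True)
class CalibrationSpec:
    """Solve one class's density value against a known total population.

    ``target_total``: animals the whole map should carry.  ``free_class``:
    the class id whose value is solved; all other presence classes keep
    their legend values.
    """

    target_total: float
    free_class: int


def calibrate_free_class(
    class_areas: Mapping[int, float], legend: Legend, spec: CalibrationSpec
) -> float:
    """Exact linear solve: v_free = (T − Σ_{c≠free} v_c·A_c) / A_free.

    ``class_areas`` holds national area (km²) per class id.  A zero free
    area is unsolvable; a negative solution is returned but flagged with a
    warning.
    """
    if spec.free_class not in legend:
        raise KeyError(f"free class {spec.free_class} not in legend")
    a_free = float(class_areas.get(spec.free_class, 0.0))
    if a_free <= 0:
        raise ValueError("free class has zero area; calibration unsolvable")
    fixed = 0.0
    for cid in legend.presence_ids:
        if cid == spec.free_class:
            continue
        fixed += legend[cid].density_value * float(class_areas.get(cid, 0.0))
    v = (spec.target_total - fixed) / a_free
    if v < 0:
        warnings.warn(f"calibrated density is negative ({v:.3g} deer/km2); "
                      "the target total is below the fixed-class population")
    return v


def _class_area_frame(zt: ZonalTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(zt, ZonalTable):
        t = zt.table.merge(zt.units[["unit_id", "state_id"]], on="unit_id")
    else:
        t = zt.copy()
        if "state_id" not in t.columns:
            t["state_id"] = ""
    return t


def estimate_population(
    zt: ZonalTable | pd.DataFrame,
    legend: Legend,
    level: str = "state",
    state_total_areas: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Population, presence area and densities at unit, state or national level.

    Input is a :class:`ZonalTable` or a DataFrame with columns unit_id,
    class_id, area_km2 (and state_id for state level).  Every presence
    class must carry a density value.  ``statewide_density`` (population /
    official total area) is filled when ``state_total_areas`` is given;
    ``presence_density`` divides by summed presence-class area.
    """
    if level not in ("unit", "state", "national"):
        raise ValueError(f"unknown level {level!r}")
    t = _class_area_frame(zt)
    values = legend.density_values()
    presence = set(legend.presence_ids)
    for cid in sorted(presence & set(t.class_id.unique())):
        if values.get(cid) is None:
            raise ValueError(f"class {cid} has no density value")
    t = t[t.class_id.isin(presence)].copy()
    t["population"] = t["area_km2"] * t["class_id"].map(values)

    key = {"unit": "unit_id", "state": "state_id", "national": None}[level]
    if key is None:
        g = pd.DataFrame({
            "population": [t["population"].sum()],
            "presence_area_km2": [t["area_km2"].sum()],
        }, index=pd.Index(["national"], name="level"))
    else:
        g = t.groupby(key).agg(population=("population", "sum"),
                               presence_area_km2=("area_km2", "sum"))
    with np.errstate(divide="ignore", invalid="ignore"):
        g["presence_density"] = np.where(
            g["presence_area_km2"] > 0,
            g["population"] / g["presence_area_km2"], np.nan)
    if state_total_areas is not None and key == "state_id":
        areas = pd.Series(state_total_areas)
        g["state_total_area_km2"] = areas.reindex(g.index)
        g["statewide_density"] = g["population"] / g["state_total_area_km2"]
    return g


def summarize_states(
    zt: ZonalTable, legend: Legend, zones: ZoneLayer
) -> pd.DataFrame:
    """State summary (population, densities, presence area) plus a national row."""
    states = estimate_population(zt, legend, "state",
                                 state_total_areas=zones.state_areas())
    nat = estimate_population(zt, legend, "national")
    total_area = float(zones.state_areas().sum())
    nat["state_total_area_km2"] = total_area
    nat["statewide_density"] = nat["population"] / total_area
    return pd.concat([states, nat.rename(index={"national": "TOTAL"})])


def national_presence_density(total_population: float,
                              total_presence_area: float) -> float:
    """Population over presence area, at the reported 0.1 deer/km² precision."""
    if total_presence_area <= 0:
        raise ValueError("presence area must be positive")
    return round(total_population / total_presence_area, 1)


@dataclass
class ComparisonTable:
    """Reported-vs-map comparison: per-state rows plus aggregates.

    difference = reported − map_estimate (so positive means the agency
    reported more animals than the map carries); quotient = reported /
    map_estimate, rounded to 2 decimals for reporting.
    """

    table: pd.DataFrame
    total_reported: float
    total_map: float
    total_difference: float
    mae: float
    unmatched: list[str]


def compare_estimates(reported: pd.Series, map_est: pd.Series) -> ComparisonTable:
    """Match states, compute differences/quotients and aggregate error stats."""
    reported = pd.Series(reported).dropna()
    map_est = pd.Series(map_est).dropna()
    common = reported.index.intersection(map_est.index)
    if len(common) == 0:
        raise ValueError("no states in common between reported and map estimates")
    unmatched = sorted(set(reported.index).symmetric_difference(map_est.index))
    r = reported.loc[common].astype(float)
    m = map_est.loc[common].astype(float)
    diff = r - m
    quot = pd.Series(np.where(m > 0, r / m, np.nan), index=common)
    table = pd.DataFrame({
        "reported": r, "map_estimate": m, "difference": diff,
        "quotient": quot.round(2),
    })
    table.index.name = "state"
    return ComparisonTable(
        table=table,
        total_reported=float(r.sum()),
        total_map=float(m.sum()),
        total_difference=float(diff.sum()),
        mae=float(diff.abs().mean()),
        unmatched=unmatched,
    )


def annual_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n−1) SD of a series of yearly estimates.

    SD is 0.0 for a single value (undefined dispersion reported as zero,
    matching how single-year series are tabulated).
    """
    vals = [float(v) for v in values if v == v]  # drop NaN
    if not vals:
        raise ValueError("no values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def count_states_at_or_above(densities: Mapping[str, float] | pd.Series,
                             threshold: float) -> int:
    """States with statewide density ≥ threshold, compared at 0.1 precision."""
    s = pd.Series(densities).astype(float)
    return int((s.round(1) >= threshold).sum())


# --------------------------------------------------------------------- data
def _load(name: str) -> pd.DataFrame:
    with resources.files("chorodig.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_state_summaries() -> pd.DataFrame:
    """Published per-state population/density/presence-area values for the
    digitized 1982 and 2003 national white-tailed deer density maps."""
    return _load("state_population_density_area_1982_2003.csv")


def load_qdma_estimates() -> pd.DataFrame:
    """QDMA 2005 state estimates alongside the 2003 map-derived estimates."""
    return _load("qdma_2005_vs_map_2003.csv")


def load_sdsg_estimates() -> pd.DataFrame:
    """Southeast Deer Study Group 2001–2005 annual state estimates, with the
    2003 map-derived estimates and QDMA 2005 values where available."""
    return _load("sdsg_annual_vs_map_2003.csv")
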