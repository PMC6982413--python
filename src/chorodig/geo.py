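"""Raster/vector I/O, affine geotransforms, and GCP-based georeferencing.

Rasters are 3-band 8-bit images with an affine geotransform mapping pixel
coordinates to projected map coordinates.  Map images published without a
georeference (plain PNG/JPG) are loaded with a unit transform and flagged,
and are georeferenced by fitting a polynomial transform to ground control
points.  Vector zone layers (counties, states) are read from GeoJSON.

Conventions: pixel coordinates are 0-based ``(col, row)``; the geotransform
maps the *outer corner* of pixel (0, 0) to ``(c, f)``, so pixel centers sit
at half-integer offsets.  The projection is carried as an opaque CRS
identifier string (default EPSG:5070, the USA Contiguous Albers Equal Area
Conic, USGS version); no datum mathematics is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

DEFAULT_CRS = "EPSG:5070"

_WORLD_EXTS = {".tif": ".tfw", ".tiff": ".tfw", ".png": ".pgw",
               ".jpg": ".jgw", ".jpeg": ".jgw"}


class Affine(NamedTuple):
    """Affine geotransform: x = a·col + b·row + c, y = d·col + e·row + f."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def identity(cls) -> "Affine":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    @classmethod
    def from_origin(cls, x0: float, y0: float, xres: float, yres: float) -> "Affine":
        """North-up grid with top-left corner (x0, y0) and pixel size (xres, yres)."""
        return cls(xres, 0.0, x0, 0.0, -yres, y0)

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in squared map units."""
        return abs(self.determinant)

    def apply(self, col, row):
        """Map continuous pixel coordinates to map coordinates."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def invert(self) -> "Affine":
        det = self.determinant
        if det == 0:
            raise ValueError("geotransform is singular")
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        return Affine(ia, ib, -(ia * self.c + ib * self.f),
                      id_, ie, -(id_ * self.c + ie * self.f))

    def pixel_centers(self, width: int, height: int):
        """Map coordinates of every pixel center, as (X, Y) arrays of shape (h, w)."""
        cols = np.arange(width) + 0.5
        rows = np.arange(height) + 0.5
        cc, rr = np.meshgrid(cols, rows)
        return self.apply(cc, rr)


@dataclass
class RasterImage:
    """A georeferenced 3-band 8-bit image.

    ``pixels`` has shape (height, width, 3), dtype uint8.  ``valid_mask``
    (optional) marks pixels carrying data; pixels outside a warp footprint
    are invalid.  ``georeferenced`` is False for images loaded without any
    world file or geotag (unit transform).
    """

    pixels: np.ndarray
    transform: Affine = field(default_factory=Affine.identity)
    crs: str = DEFAULT_CRS
    valid_mask: np.ndarray | None = None
    georeferenced: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (h, w, 3) pixels, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.transform.determinant == 0:
            raise ValueError("geotransform must be invertible")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.pixels.shape[:2]:
                raise ValueError("valid_mask shape mismatch")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.pixels[..., 0], self.pixels[..., 1], self.pixels[..., 2]

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_area

    def mask(self) -> np.ndarray:
        """Boolean validity mask (all-True when no mask is set)."""
        if self.valid_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid_mask


class GroundControlPoint(NamedTuple):
    """Correspondence between an image pixel and a projected map coordinate."""

    src_col: float
    src_row: float
    map_x: float
    map_y: float


def _monomial_exponents(order: int) -> list[tuple[int, int]]:
    """Exponent pairs (i, j) of col^i·row^j with i + j <= order, in a fixed order."""
    return [(d - j, j) for d in range(order + 1) for j in range(d + 1)]


def _design_matrix(u: np.ndarray, v: np.ndarray, order: int) -> np.ndarray:
    return np.column_stack([u**i * v**j for i, j in _monomial_exponents(order)])


@dataclass
class PolynomialTransform:
    """Polynomial georeferencing transform fitted to ground control points.

    Stores both directions: ``coeffs_x/coeffs_y`` map (col, row) to (x, y),
    and ``inv_coeffs_x/inv_coeffs_y`` map (x, y) back to (col, row); both
    are least-squares fits to the same GCPs (the inverse of a polynomial of
    order > 1 has no closed form).  ``rms_residual`` is the forward root
    mean square error over the GCPs, in map units.
    """

    order: int
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    inv_coeffs_x: np.ndarray | None
    inv_coeffs_y: np.ndarray | None
    rms_residual: float

    def forward(self, col, row):
        A = _design_matrix(np.asarray(col, float).ravel(),
                           np.asarray(row, float).ravel(), self.order)
        shape = np.asarray(col).shape
        return (A @ self.coeffs_x).reshape(shape), (A @ self.coeffs_y).reshape(shape)

    def inverse(self, x, y):
        if self.inv_coeffs_x is None or self.inv_coeffs_y is None:
            raise ValueError(
                "no inverse mapping: the GCP configuration was degenerate in "
                "map space; refit with more or better-spread control points")
        A = _design_matrix(np.asarray(x, float).ravel(),
                           np.asarray(y, float).ravel(), self.order)
        shape = np.asarray(x).shape
        return (A @ self.inv_coeffs_x).reshape(shape), (A @ self.inv_coeffs_y).reshape(shape)


class DegenerateGCPError(ValueError):
    """GCP configuration does not determine the transform (e.g. collinear points)."""


def n_coefficients(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def fit_polynomial_transform(
    gcps: Sequence[GroundControlPoint], order: int = 3
) -> PolynomialTransform:
    """Fit a polynomial map-registration transform to ground control points.

    Ordinary least squares per axis over all monomials col^i·row^j with
    i + j <= ``order`` (order 1-3, requiring 3/6/10 points).  No outlier
    rejection is performed; inspect ``rms_residual`` instead.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    need = n_coefficients(order)
    if len(gcps) < need:
        raise ValueError(
            f"order {order} requires at least {need} GCPs, got {len(gcps)}"
        )
    arr = np.asarray([(g.src_col, g.src_row, g.map_x, g.map_y) for g in gcps], float)
    if not np.isfinite(arr).all():
        raise ValueError("GCP coordinates must be finite")
    col, row, x, y = arr.T

    A = _design_matrix(col, row, order)
    if np.linalg.matrix_rank(A) < need:
        raise DegenerateGCPError(
            "GCP configuration is degenerate (rank-deficient design matrix)"
        )
    cx, *_ = np.linalg.lstsq(A, x, rcond=None)
    cy, *_ = np.linalg.lstsq(A, y, rcond=None)

    # inverse (map -> pixel) fit is best-effort: a configuration can determine
    # the forward map yet be rank-deficient in map space (inverse only needed
    # for warping)
    B = _design_matrix(x, y, order)
    if np.linalg.matrix_rank(B) >= need:
        icx, *_ = np.linalg.lstsq(B, col, rcond=None)
        icy, *_ = np.linalg.lstsq(B, row, rcond=None)
    else:
        icx = icy = None

    res = np.hypot(A @ cx - x, A @ cy - y)
    rms = float(np.sqrt(np.mean(res**2)))
    return PolynomialTransform(order, cx, cy, icx, icy, rms)


def read_gcps(path: str | Path) -> list[GroundControlPoint]:
    """Read a GCP table with columns src_col, src_row, map_x, map_y."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = ["src_col", "src_row", "map_x", "map_y"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"GCP table missing columns {missing}")
    return [GroundControlPoint(*r) for r in df[cols].to_numpy(float)]


def warp_image(
    img: RasterImage,
    transform: PolynomialTransform,
    out_transform: Affine,
    out_shape: tuple[int, int],
    crs: str | None = None,
) -> RasterImage:
    """Resample a map image onto a target grid through a fitted transform.

    Nearest-neighbor only: interpolation would invent colors absent from
    the legend palette.  Output pixels whose inverse mapping falls outside
    the source image (or on invalid source pixels) are marked invalid.
    """
    h, w = out_shape
    X, Y = out_transform.pixel_centers(w, h)
    scol, srow = transform.inverse(X, Y)
    ci = np.floor(scol).astype(np.int64)
    ri = np.floor(srow).astype(np.int64)
    ok = (ci >= 0) & (ci < img.width) & (ri >= 0) & (ri < img.height)
    ok &= np.isfinite(scol) & np.isfinite(srow)
    out = np.zeros((h, w, 3), dtype=np.uint8)
    src_mask = img.mask()
    cc = np.clip(ci, 0, img.width - 1)
    rr = np.clip(ri, 0, img.height - 1)
    sampled = img.pixels[rr, cc]
    valid = ok & src_mask[rr, cc]
    out[valid] = sampled[valid]
    return RasterImage(out, out_transform, crs or img.crs, valid_mask=valid)


# --------------------------------------------------------------------------
# Raster I/O: TIFF via tifffile (+ basic GeoTIFF tags), PNG/JPG via Pillow,
# always with an ESRI world file sidecar; CRS in a small .aux.json sidecar.
# --------------------------------------------------------------------------

def _world_path(path: Path) -> Path:
    return path.with_suffix(_WORLD_EXTS.get(path.suffix.lower(), ".wld"))


def _write_world_file(path: Path, t: Affine) -> None:
    cx, cy = t.apply(0.5, 0.5)  # world files reference the first pixel *center*
    lines = [t.a, t.d, t.b, t.e, float(cx), float(cy)]
    _world_path(path).write_text("".join(f"{v:.10f}\n" for v in lines))


def _read_world_file(path: Path) -> Affine | None:
    for cand in (_world_path(path), path.with_suffix(".wld")):
        if cand.exists():
            vals = [float(v) for v in cand.read_text().split()]
            if len(vals) != 6:
                raise ValueError(f"malformed world file {cand}")
            a, d, b, e, cx, cy = vals
            return Affine(a, b, cx - 0.5 * a - 0.5 * b, d, e, cy - 0.5 * d - 0.5 * e)
    return None


def _aux_path(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def write_raster(img: RasterImage, path: str | Path) -> None:
    """Write a 3-band raster with world-file georeference (TIFF/PNG)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        extratags = []
        t = img.transform
        if t.b == 0 and t.d == 0:  # north-up: encode standard GeoTIFF scale/tiepoint
            extratags = [
                (33550, "d", 3, (abs(t.a), abs(t.e), 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
            ]
        tifffile.imwrite(path, img.pixels, photometric="rgb", extratags=extratags)
    elif suffix in (".png", ".jpg", ".jpeg"):
        from PIL import Image

        Image.fromarray(img.pixels).save(path)
    else:
        raise ValueError(f"unsupported raster format {suffix!r}")
    _write_world_file(path, img.transform)
    _aux_path(path).write_text(json.dumps({"crs": img.crs}))


def read_raster(path: str | Path) -> RasterImage:
    """Read a 3-band raster; look for a world file, else flag ungeoreferenced."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[..., :3]

    t = _read_world_file(path)
    georef = t is not None
    if t is None and suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            tags = tf.pages[0].tags
            if 33550 in tags and 33922 in tags:
                sx, sy, _ = tags[33550].value[:3]
                tp = tags[33922].value[:6]
                t = Affine(sx, 0.0, tp[3] - tp[0] * sx, 0.0, -sy, tp[4] + tp[1] * sy)
                georef = True
    if t is None:
        warnings.warn(f"{path.name}: no georeference found; using unit transform")
        t = Affine.identity()
    crs = DEFAULT_CRS
    aux = _aux_path(path)
    if aux.exists():
        crs = json.loads(aux.read_text()).get("crs", DEFAULT_CRS)
    return RasterImage(arr.astype(np.uint8), t, crs, georeferenced=georef)


def write_labels(labels: np.ndarray, transform: Affine, path: str | Path,
                 crs: str = DEFAULT_CRS) -> None:
    """Write a single-band 32-bit integer label/class raster (TIFF)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    _write_world_file(path, transform)
    _aux_path(path).write_text(json.dumps({"crs": crs}))


def read_labels(path: str | Path) -> tuple[np.ndarray, Affine, str]:
    path = Path(path)
    arr = tifffile.imread(path).astype(np.int32)
    t = _read_world_file(path) or Affine.identity()
    crs = DEFAULT_CRS
    aux = _aux_path(path)
    if aux.exists():
        crs = json.loads(aux.read_text()).get("crs", DEFAULT_CRS)
    return arr, t, crs


# --------------------------------------------------------------------------
# Vector zones
# --------------------------------------------------------------------------

@dataclass
class ZoneLayer:
    """Polygon analysis units (counties or states) with official areas.

    ``units`` is a DataFrame with columns ``unit_id`` (str), ``state_id``
    (str), ``geometry`` (shapely polygon, projected meters) and
    ``official_area_km2`` (float > 0).  Official areas default to geometry
    area when the source layer does not provide them.
    """

    units: pd.DataFrame
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        req = ["unit_id", "state_id", "geometry", "official_area_km2"]
        missing = [c for c in req if c not in self.units.columns]
        if missing:
            raise ValueError(f"ZoneLayer missing columns {missing}")
        if self.units["unit_id"].duplicated().any():
            dupes = self.units.loc[self.units.unit_id.duplicated(), "unit_id"].tolist()
            raise ValueError(f"duplicate unit ids: {dupes}")
        if (self.units["official_area_km2"] <= 0).any():
            raise ValueError("official_area_km2 must be positive")
        geoms = [
            g if g.is_valid else shapely.make_valid(g)
            for g in self.units["geometry"]
        ]
        self.units = self.units.assign(geometry=geoms).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return self.units["unit_id"].tolist()

    def geometry(self, unit_id: str):
        row = self.units.loc[self.units.unit_id == unit_id]
        if row.empty:
            raise KeyError(f"unknown unit {unit_id!r}")
        return row.iloc[0].geometry

    def state_areas(self) -> pd.Series:
        """Official area per state (km2), summed over member units."""
        return self.units.groupby("state_id")["official_area_km2"].sum()


def read_zones(path: str | Path) -> ZoneLayer:
    """Read a polygon zone layer from GeoJSON."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    rows = []
    for i, feat in enumerate(payload["features"]):
        props = feat.get("properties") or {}
        geom = geom_shape(feat["geometry"])
        area = props.get("official_area_km2", props.get("area_km2"))
        if area is None:
            area = geom.area / 1e6
        rows.append(
            {
                "unit_id": str(props.get("unit_id", props.get("FIPS", i))),
                "state_id": str(props.get("state_id", props.get("STATE", ""))),
                "geometry": geom,
                "official_area_km2": float(area),
            }
        )
    crs = payload.get("crs_id", DEFAULT_CRS)
    return ZoneLayer(pd.DataFrame(rows), crs=crs)


def write_vector(layer: ZoneLayer, path: str | Path,
                 extra: pd.DataFrame | None = None) -> None:
    """Write a zone layer to GeoJSON, optionally joining extra attributes."""
    units = layer.units
    if extra is not None:
        units = units.merge(extra, on="unit_id", how="left")
    feats = []
    for _, row in units.iterrows():
        props = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in row.drop("geometry").items()
        }
        feats.append(
            {"type": "Feature", "properties": props,
             "geometry": geom_mapping(row.geometry)}
        )
    payload = {"type": "FeatureCollection", "crs_id": layer.crs, "features": feats}
    Path(path).write_text(json.dumps(payload))
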