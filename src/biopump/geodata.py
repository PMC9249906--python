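"""Gridded and zonal geodata handling.

Rasters are held as :class:`RasterLayer` — a 2-D value grid plus an affine
grid→world mapping, a CRS identifier, a nodata sentinel and a categorical /
continuous flag. Two on-disk formats are supported:

* ESRI ASCII grid (``.asc``) with an optional ``.prj`` sidecar carrying the
  CRS string — plain text, round-trips integer grids bit-exactly;
* GeoTIFF (``.tif``/``.tiff``) through :mod:`tifffile`, writing and parsing
  the ModelPixelScale, ModelTiepoint, GeoKeyDirectory and GDAL_NODATA tags.

Grid convention: cell centers, row 0 is the northernmost row, axis-aligned
north-up grids only. Cross-layer operations require both layers on the same
grid (use :func:`align_to_grid` first); no implicit resampling ever happens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GridTransform",
    "RasterLayer",
    "read_raster",
    "write_raster",
    "align_to_grid",
    "zonal_aggregate",
    "cell_area_ha",
    "combine_zone_codes",
]

#: mean meters per degree of great-circle arc (authalic Earth radius)
_M_PER_DEG = 111_194.93


class GeodataError(ValueError):
    """Raised for malformed rasters, grid mismatches and unknown CRS."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine mapping between array indices and world coordinates.

    ``x0, y0`` are the coordinates of the *outer corner* of cell (0, 0)
    (west edge of column 0, north edge of row 0); ``dx, dy`` are positive
    cell sizes in CRS units.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise GeodataError("cell sizes must be positive (transform must be invertible)")

    def cell_center(self, row, col):
        """World coordinates (x, y) of cell centers for array indices."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def world_to_index(self, x, y):
        """Fractional (row, col) for world coordinates; floor to get cells."""
        col = (np.asarray(x) - self.x0) / self.dx
        row = (self.y0 - np.asarray(y)) / self.dy
        return row, col


@dataclass
class RasterLayer:
    """A single-band georeferenced grid."""

    values: np.ndarray
    transform: GridTransform
    crs: str
    nodata: float
    kind: str = "continuous"  # or "categorical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise GeodataError("raster values must be a non-empty 2-D grid")
        if self.kind not in ("continuous", "categorical"):
            raise GeodataError(f"unknown raster kind: {self.kind!r}")
        if not self.crs:
            raise GeodataError("raster must carry a CRS identifier")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds a real value."""
        v = self.values
        mask = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            mask &= ~np.isnan(v)
        return mask

    def same_grid(self, other: "RasterLayer") -> bool:
        t, u = self.transform, other.transform
        return self.shape == other.shape and self.crs == other.crs and (
            math.isclose(t.x0, u.x0) and math.isclose(t.y0, u.y0)
            and math.isclose(t.dx, u.dx) and math.isclose(t.dy, u.dy)
        )

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "RasterLayer":
        return replace(self, values=np.asarray(values), kind=kind or self.kind)


def _is_geographic(crs: str) -> bool:
    c = crs.upper().replace(" ", "")
    return any(tok in c for tok in ("4326", "CRS84", "WGS84", "GEOGRAPHIC", "LONLAT", "LATLON"))


def cell_area_ha(layer: RasterLayer) -> np.ndarray:
    """Per-cell area in hectares.

    Geographic CRSs use a cosine-of-latitude geodesic approximation (cell
    width shrinks toward the poles); projected CRSs are assumed to be in
    meters so every cell has the same area.
    """
    t = layer.transform
    nrow, ncol = layer.shape
    if _is_geographic(layer.crs):
        _, lat = t.cell_center(np.arange(nrow), 0)
        h = t.dy * _M_PER_DEG
        w = t.dx * _M_PER_DEG * np.cos(np.radians(lat))
        col_area = (h * w) / 1e4
        return np.repeat(col_area[:, None], ncol, axis=1)
    return np.full((nrow, ncol), t.dx * t.dy / 1e4)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_raster(path, *, kind: str | None = None, crs: str | None = None) -> RasterLayer:
    """Read a georeferenced grid (``.asc`` or GeoTIFF).

    ``kind`` overrides the categorical/continuous flag; ``crs`` overrides
    whatever the file (or its ``.prj`` sidecar) declares.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        layer = _read_asc(path)
    elif suffix in (".tif", ".tiff"):
        layer = _read_geotiff(path)
    else:
        raise GeodataError(f"unsupported raster format: {path.name}")
    if crs is not None:
        layer = replace(layer, crs=crs)
    if kind is not None:
        layer = replace(layer, kind=kind)
    return layer


def write_raster(layer: RasterLayer, path) -> Path:
    """Write a :class:`RasterLayer` to ``.asc`` (+ ``.prj``) or GeoTIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_asc(layer, path)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(layer, path)
    else:
        raise GeodataError(f"unsupported raster format: {path.name}")
    return path


def _read_asc(path: Path) -> RasterLayer:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise GeodataError(f"{path.name}: not an ASCII grid ({exc})") from exc
    required = {"ncols", "nrows", "cellsize"}
    if not required.issubset(header) or not rows:
        raise GeodataError(f"{path.name}: missing ASCII-grid header or data")
    values = np.array(rows)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise GeodataError(f"{path.name}: data shape {values.shape} != header ({nrows}, {ncols})")
    cs = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cs / 2
    else:
        raise GeodataError(f"{path.name}: no x origin in header")
    yll = header.get("yllcorner", header.get("yllcenter", np.nan) - cs / 2)
    if np.isnan(yll):
        raise GeodataError(f"{path.name}: no y origin in header")
    nodata = header.get("nodata_value", -9999.0)
    prj = path.with_suffix(".prj")
    crs = prj.read_text().strip() if prj.exists() else "EPSG:4326"
    transform = GridTransform(x0=x0, y0=yll + nrows * cs, dx=cs, dy=cs)
    return RasterLayer(values=values, transform=transform, crs=crs, nodata=nodata)


def _write_asc(layer: RasterLayer, path: Path) -> None:
    t = layer.transform
    if not math.isclose(t.dx, t.dy):
        raise GeodataError("ASCII grids require square cells")
    nrows, ncols = layer.shape
    v = np.asarray(layer.values)
    integral = np.issubdtype(v.dtype, np.integer) or (
        np.all(np.isfinite(v)) and np.all(v == np.trunc(v))
    )
    fmt = "%d" if integral else "%.10g"
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {t.x0:.10g}\nyllcorner {t.y0 - nrows * t.dy:.10g}\n")
        fh.write(f"cellsize {t.dx:.10g}\nnodata_value {layer.nodata:.10g}\n")
        np.savetxt(fh, v, fmt=fmt)
    path.with_suffix(".prj").write_text(layer.crs + "\n")


def _epsg_code(crs: str) -> int:
    c = crs.upper().replace(" ", "")
    if c.startswith("EPSG:"):
        return int(c.split(":")[1])
    if _is_geographic(crs):
        return 4326
    raise GeodataError(f"cannot express CRS {crs!r} as an EPSG code for GeoTIFF")


def _write_geotiff(layer: RasterLayer, path: Path) -> None:
    import tifffile

    t = layer.transform
    epsg = _epsg_code(layer.crs)
    model_type = 2 if _is_geographic(layer.crs) else 1
    geokeys = [1, 1, 0, 2, 1024, 0, 1, model_type,
               2048 if model_type == 2 else 3072, 0, 1, epsg]
    extratags = [
        (33550, "d", 3, (t.dx, t.dy, 0.0), False),          # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0), False),  # ModelTiepoint
        (34735, "H", len(geokeys), tuple(geokeys), False),   # GeoKeyDirectory
        (42113, "s", 0, str(layer.nodata), False),           # GDAL_NODATA
    ]
    desc = f"kind={layer.kind}"
    tifffile.imwrite(path, np.asarray(layer.values), extratags=extratags, description=desc)


def _read_geotiff(path: Path) -> RasterLayer:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            tagvals = {code: tag.value for code, tag in page.tags.items()}
    except Exception as exc:  # noqa: BLE001 - any parse failure is a format error
        raise GeodataError(f"{path.name}: not a readable TIFF ({exc})") from exc
    if 33550 not in tagvals or 33922 not in tagvals:
        raise GeodataError(f"{path.name}: TIFF has no georeferencing tags")
    sx, sy = tagvals[33550][0], tagvals[33550][1]
    tp = tagvals[33922]
    x0 = tp[3] - tp[0] * sx
    y0 = tp[4] + tp[1] * sy
    crs = "EPSG:4326"
    if 34735 in tagvals:
        gk = list(tagvals[34735])
        for i in range(4, len(gk), 4):
            if gk[i] in (2048, 3072):
                crs = f"EPSG:{gk[i + 3]}"
    nodata = -9999.0
    if 42113 in tagvals:
        nodata = float(str(tagvals[42113]).strip("\x00 "))
    kind = "continuous"
    if "kind=categorical" in str(tagvals.get(270, "")):
        kind = "categorical"
    return RasterLayer(values=values, transform=GridTransform(x0, y0, sx, sy),
                       crs=crs, nodata=nodata, kind=kind)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _overlap_matrix(ref_edges: np.ndarray, src_edges: np.ndarray) -> np.ndarray:
    """Length of interval overlap between every ref cell and every src cell."""
    lo = np.maximum(ref_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(ref_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def align_to_grid(layer: RasterLayer, reference: RasterLayer) -> RasterLayer:
    """Resample ``layer`` onto ``reference``'s grid.

    Categorical layers use nearest-neighbour sampling at the reference cell
    center; continuous layers use an area-weighted mean of the overlapping
    source cells. Nodata propagates; reference cells falling entirely
    outside the source extent become nodata.
    """
    if layer.crs != reference.crs:
        raise GeodataError(
            f"CRS mismatch: {layer.crs!r} vs {reference.crs!r}; reprojection is unsupported"
        )
    if layer.same_grid(reference):
        return layer
    t, r = layer.transform, reference.transform
    nrow_r, ncol_r = reference.shape
    nrow_s, ncol_s = layer.shape

    if layer.kind == "categorical":
        xc, _ = r.cell_center(0, np.arange(ncol_r))
        _, yc = r.cell_center(np.arange(nrow_r), 0)
        rows_f, _ = t.world_to_index(t.x0, yc)
        _, cols_f = t.world_to_index(xc, t.y0)
        rows = np.floor(rows_f).astype(int)
        cols = np.floor(cols_f).astype(int)
        ok_r = (rows >= 0) & (rows < nrow_s)
        ok_c = (cols >= 0) & (cols < ncol_s)
        out = np.full((nrow_r, ncol_r), layer.nodata, dtype=np.asarray(layer.values).dtype)
        rr = rows[ok_r]
        cc = cols[ok_c]
        out[np.ix_(ok_r, ok_c)] = np.asarray(layer.values)[np.ix_(rr, cc)]
        return RasterLayer(out, r, reference.crs, layer.nodata, "categorical")

    # continuous: separable area-weighted mean via row/col overlap matrices
    src_x = t.x0 + np.arange(ncol_s + 1) * t.dx
    src_y = t.y0 - np.arange(nrow_s + 1) * t.dy
    ref_x = r.x0 + np.arange(ncol_r + 1) * r.dx
    ref_y = r.y0 - np.arange(nrow_r + 1) * r.dy
    wc = _overlap_matrix(ref_x, src_x)                     # (ncol_r, ncol_s)
    wr = _overlap_matrix(-ref_y, -src_y)                   # (nrow_r, nrow_s)
    v = np.asarray(layer.values, dtype=float)
    m = layer.valid_mask().astype(float)
    num = wr @ np.where(m > 0, v, 0.0) @ wc.T
    den = wr @ m @ wc.T
    out = np.full((nrow_r, ncol_r), float(layer.nodata))
    good = den > 0
    out[good] = num[good] / den[good]
    return RasterLayer(out, r, reference.crs, float(layer.nodata), "continuous")


# ---------------------------------------------------------------------------
# Zonal aggregation
# ---------------------------------------------------------------------------

_ZONE_FACTOR = 100_000


def combine_zone_codes(regions: RasterLayer, gez: RasterLayer) -> RasterLayer:
    """Fuse a region raster and a GEZ raster into one coded zone raster.

    Combined code = region_id * 100000 + gez_id; decode with
    ``divmod(code, 100000)``. Cells missing either id become nodata.
    """
    if not regions.same_grid(gez):
        raise GeodataError("region and GEZ rasters must share a grid")
    ok = regions.valid_mask() & gez.valid_mask()
    code = np.where(
        ok,
        np.asarray(regions.values, dtype=np.int64) * _ZONE_FACTOR
        + np.asarray(gez.values, dtype=np.int64),
        -1,
    )
    return RasterLayer(code, regions.transform, regions.crs, -1, "categorical")


def split_zone_code(code: int) -> tuple[int, int]:
    return divmod(int(code), _ZONE_FACTOR)


def zonal_aggregate(
    values: RasterLayer,
    zones: RasterLayer,
    stat: str,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate a value raster inside each zone of a coded zone raster.

    ``stat`` is one of ``mean`` (weight-averaged over valid cells), ``sum``
    (weighted sum) or ``mode`` (weighted modal category, ties broken by the
    smallest code). Returns a DataFrame indexed by zone code with a single
    column named after the stat; zones whose cells are all missing are
    absent from the result, never reported as zero.
    """
    if not values.same_grid(zones):
        raise GeodataError("values and zones must share a grid")
    if stat not in ("mean", "sum", "mode"):
        raise GeodataError(f"unknown stat: {stat!r}")
    w = np.ones(values.shape) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != values.shape:
        raise GeodataError("weights must match the grid shape")
    ok = values.valid_mask() & zones.valid_mask()
    z = np.asarray(zones.values)[ok].astype(np.int64)
    v = np.asarray(values.values, dtype=float)[ok]
    ww = w[ok]
    out: dict[int, float] = {}
    for code in np.unique(z):
        sel = z == code
        if stat == "mean":
            tw = ww[sel].sum()
            if tw <= 0:
                continue
            out[int(code)] = float(np.sum(v[sel] * ww[sel]) / tw)
        elif stat == "sum":
            out[int(code)] = float(np.sum(v[sel] * ww[sel]))
        else:  # mode
            cats, inv = np.unique(v[sel], return_inverse=True)
            mass = np.bincount(inv, weights=ww[sel])
            out[int(code)] = float(cats[np.argmax(mass)])  # argmax → smallest code on tie
    df = pd.DataFrame({stat: pd.Series(out, dtype=float)})
    df.index.name = "zone"
    return df
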