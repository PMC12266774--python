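"""Planar raster grids and GeoTIFF I/O.

``RasterGrid`` is the carrier for every mapped quantity in the pipeline:
elevation, monthly temperature, bioclim variables, suitability, metabolic
rate, vapor pressure deficit, resistance, and all boolean masks.  Grids are
projected (meter units), row 0 is the northern edge, and cell centers sit at
``origin + (index + 1/2) * cell_size``.  All point-in-cell tests use
half-open cell intervals so every point belongs to exactly one cell.

GeoTIFF files are written with :mod:`tifffile`, carrying the standard
``ModelPixelScale``, ``ModelTiepoint``, ``GeoKeyDirectory`` and
``GDAL_NODATA`` tags; geographic (lat/lon) rasters are rejected on read
because the analysis is strictly planar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import GridMismatchError, RasterIOError

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

_GEOTOL = 1e-6


@dataclass
class RasterGrid:
    """A single-band raster on a projected, north-up grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values. Stored as float64 unless boolean/integer semantics are
        needed by the caller (masks and labels also ride in this carrier).
    cell_size : float
        Cell edge length in meters (> 0; square cells).
    origin : (float, float)
        Map coordinates (x0, y0) of the *upper-left corner* of cell (0, 0).
    nodata_mask : ndarray of bool, same shape
        True where the cell carries no data. Arithmetic helpers propagate
        nodata: an output cell is nodata wherever any input is.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return ~self.nodata_mask

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= _GEOTOL
            and abs(self.origin[0] - other.origin[0]) <= _GEOTOL
            and abs(self.origin[1] - other.origin[1]) <= _GEOTOL
        )

    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid with this grid's geometry and the given values."""
        mask = self.nodata_mask.copy() if nodata_mask is None else np.asarray(nodata_mask, bool)
        return RasterGrid(np.asarray(values), self.cell_size, self.origin, mask)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.cell_size, self.origin, self.nodata_mask.copy())

    # -- coordinates -------------------------------------------------------

    def cell_center(self, rows, cols):
        """Map coordinates of cell centers for (arrays of) indices."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(cols) + 0.5) * self.cell_size
        y = y0 - (np.asarray(rows) + 0.5) * self.cell_size
        return x, y

    def point_to_rc(self, x, y):
        """Row/col indices of the cells containing points (half-open cells)."""
        x0, y0 = self.origin
        cols = np.floor((np.asarray(x, float) - x0) / self.cell_size).astype(np.int64)
        rows = np.floor((y0 - np.asarray(y, float)) / self.cell_size).astype(np.int64)
        return rows, cols

    def contains(self, x, y):
        rows, cols = self.point_to_rc(x, y)
        nr, nc = self.shape
        return (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)

    def values_at(self, points: np.ndarray):
        """Extract values at (n, 2) map-coordinate points.

        Returns ``(values, ok)`` where ``ok`` flags points that fall inside
        the extent on non-nodata cells; values at bad points are NaN.
        """
        pts = np.asarray(points, float).reshape(-1, 2)
        rows, cols = self.point_to_rc(pts[:, 0], pts[:, 1])
        nr, nc = self.shape
        inside = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
        out = np.full(len(pts), np.nan)
        ok = inside.copy()
        r, c = rows[inside], cols[inside]
        vals = self.values[r, c].astype(float)
        bad = self.nodata_mask[r, c]
        vals[bad] = np.nan
        out[inside] = vals
        ok[inside] = ~bad
        return out, ok

    # -- masked statistics ---------------------------------------------------

    def masked_values(self) -> np.ndarray:
        """1-D array of the values on non-nodata cells."""
        return self.values[self.valid]


def require_same_grid(*grids: RasterGrid) -> None:
    """Raise :class:`GridMismatchError` unless all grids share geometry."""
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise GridMismatchError(
                f"grid geometry mismatch: {ref.shape}@{ref.cell_size} vs {g.shape}@{g.cell_size}"
            )


def combined_mask(*grids: RasterGrid) -> np.ndarray:
    """Union of the nodata masks (for nodata-propagating arithmetic)."""
    m = grids[0].nodata_mask.copy()
    for g in grids[1:]:
        m |= g.nodata_mask
    return m


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

# Minimal GeoKeyDirectory declaring a projected CRS with meter units:
#   GTModelTypeGeoKey (1024) = 1 (projected)
#   GTRasterTypeGeoKey (1025) = 1 (pixel is area)
#   ProjLinearUnitsGeoKey (3076) = 9001 (metre)
_PROJECTED_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3076, 0, 1, 9001)


def _geo_extratags(grid: RasterGrid, nodata: float):
    cs = float(grid.cell_size)
    x0, y0 = grid.origin
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_PROJECTED_GEOKEYS), _PROJECTED_GEOKEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]


def write_raster(grid: RasterGrid, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a single-band float32 GeoTIFF with nodata tagged."""
    vals = grid.values.astype(np.float32).copy()
    vals[grid.nodata_mask] = np.float32(nodata)
    tifffile.imwrite(str(path), vals, extratags=_geo_extratags(grid, nodata))


def write_raster_stack(grids: list[RasterGrid], names: list[str], path,
                       nodata: float = DEFAULT_NODATA) -> None:
    """Write aligned grids as a multi-band GeoTIFF; band names go in the
    image description as JSON."""
    require_same_grid(*grids)
    if len(names) != len(grids):
        raise ValueError("one name per band required")
    arr = np.stack([g.values.astype(np.float32) for g in grids])
    for k, g in enumerate(grids):
        arr[k][g.nodata_mask] = np.float32(nodata)
    tifffile.imwrite(
        str(path),
        arr,
        extratags=_geo_extratags(grids[0], nodata),
        description=json.dumps({"bands": list(names)}),
    )


def _parse_geotags(page, path):
    tags = page.tags
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise RasterIOError(f"{path}: missing GeoTIFF georeferencing tags")
    if _TAG_GEO_KEYS in tags:
        keys = tuple(tags[_TAG_GEO_KEYS].value)
        # key entries follow the 4-value header in groups of 4
        for k in range(4, len(keys) - 3, 4):
            if keys[k] == 1024 and keys[k + 3] == 2:
                raise RasterIOError(f"{path}: geographic CRS rasters are not supported")
    scale = tags[_TAG_PIXEL_SCALE].value
    tie = tags[_TAG_TIEPOINT].value
    if abs(scale[0] - scale[1]) > _GEOTOL:
        raise RasterIOError(f"{path}: non-square cells are not supported")
    cell = float(scale[0])
    # tiepoint maps raster (i, j, k) -> model (x, y, z)
    x0 = float(tie[3]) - float(tie[0]) * cell
    y0 = float(tie[4]) + float(tie[1]) * cell
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        except (TypeError, ValueError):
            nodata = None
    return cell, (x0, y0), nodata


def read_raster(path) -> RasterGrid:
    """Read a single-band projected GeoTIFF into a :class:`RasterGrid`."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            cell, origin, nodata = _parse_geotags(page, path)
            arr = tf.asarray()
    except RasterIOError:
        raise
    except Exception as exc:  # unreadable / not a TIFF
        raise RasterIOError(f"{path}: cannot read raster ({exc})") from exc
    if arr.ndim == 3:
        raise RasterIOError(f"{path}: multi-band file; use read_raster_stack")
    vals = arr.astype(float)
    mask = np.zeros(vals.shape, bool) if nodata is None else np.isclose(vals, nodata)
    return RasterGrid(vals, cell, origin, mask)


def read_raster_stack(path) -> tuple[list[RasterGrid], list[str]]:
    """Read a multi-band GeoTIFF written by :func:`write_raster_stack`."""
    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            cell, origin, nodata = _parse_geotags(page, path)
            arr = tf.asarray()
            desc = page.tags.get("ImageDescription")
            names = None
            if desc is not None:
                try:
                    names = json.loads(desc.value).get("bands")
                except (ValueError, AttributeError):
                    names = None
    except RasterIOError:
        raise
    except Exception as exc:
        raise RasterIOError(f"{path}: cannot read raster ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None]
    grids = []
    for band in arr:
        vals = band.astype(float)
        mask = np.zeros(vals.shape, bool) if nodata is None else np.isclose(vals, nodata)
        grids.append(RasterGrid(vals, cell, origin, mask))
    if names is None:
        names = [f"band{k + 1}" for k in range(len(grids))]
    return grids, names
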