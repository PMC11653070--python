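"""Geographic grid data model, raster I/O, resampling and spherical area math.

All grids are geographic (WGS84 degrees), north-up: row 0 is the northernmost
row.  Cell centers sit at ``(x_min + (j+0.5)*cell, y_max - (i+0.5)*cell)`` and
point-in-cell tests use half-open intervals ``[edge, edge + cell)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: default working resolution, 2.5 arcminutes
DEFAULT_CELL_SIZE = 2.5 / 60.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic raster grid with square cells."""

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    nodata: float = -9999.0
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.y_min < -90 or self.y_max > 90:
            raise ValueError("latitude bounds must lie within [-90, 90]")
        if self.x_max - self.x_min > 360 + 1e-9:
            raise ValueError("longitudinal extent exceeds 360 degrees")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 northernmost."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """Row/col indices of the cells containing the given points.

        Points outside the grid get index -1.  Half-open convention: a point
        exactly on a cell's west/south edge belongs to that cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_min) / self.cell_size).astype(int)
        # measure from the south edge so [edge, edge+cell) holds exactly
        row = self.n_rows - 1 - np.floor(
            (lat - self.y_min) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class RasterLayer:
    """One named environmental variable (or model surface) on a grid."""

    spec: GridSpec
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"layer '{self.name}': values shape {self.values.shape} does not "
                f"match spec ({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.spec.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.spec, name or self.name, values)


class RasterStack:
    """Ordered collection of layers sharing one GridSpec and one nodata mask."""

    def __init__(self, layers: list[RasterLayer]):
        if not layers:
            raise ValueError("empty stack")
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        spec = layers[0].spec
        for l in layers[1:]:
            if not spec.same_geometry(l.spec):
                raise ValueError(f"layer '{l.name}' is not on the shared grid")
        self.spec = spec
        self.layers = list(layers)
        self._index = {l.name: l for l in layers}

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> RasterLayer:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no layer named '{name}' in stack {self.names}") from None

    @property
    def mask(self) -> np.ndarray:
        m = self.layers[0].mask
        for l in self.layers[1:]:
            m &= l.mask
        return m

    def values_at(self, lon, lat) -> np.ndarray:
        """Matrix of layer values at points; NaN for off-grid or nodata cells."""
        row, col = self.spec.cell_of(lon, lat)
        out = np.full((np.size(row), len(self.layers)), np.nan)
        ok = row >= 0
        for k, l in enumerate(self.layers):
            v = l.values[row[ok], col[ok]]
            v = np.where(v == self.spec.nodata, np.nan, v)
            out[ok, k] = v
        return out

    def table(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix over the (optionally given) mask."""
        m = self.mask if mask is None else mask
        return np.column_stack([l.values[m] for l in self.layers])

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack([self._index[n] for n in names])


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid and GeoTIFF

def _parse_ascii_header(lines: list[str], path) -> dict:
    header = {}
    for ln in lines:
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed header line {ln!r}")
        key = parts[0].lower()
        header[key] = parts[1]
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing required header field '{req}'")
    if "xllcorner" not in header or "yllcorner" not in header:
        raise ValueError(f"{path}: only corner-registered grids supported "
                         "(xllcorner/yllcorner)")
    return header


def read_esri_ascii(path, name: str | None = None) -> RasterLayer:
    path = Path(path)
    with open(path) as fh:
        text = fh.read().split("\n")
    header_lines, i = [], 0
    while i < len(text) and text[i].strip() and not _is_number_row(text[i]):
        header_lines.append(text[i])
        i += 1
    header = _parse_ascii_header(header_lines, path)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    nodata = float(header.get("nodata_value", -9999))
    body = " ".join(text[i:])
    values = (np.array(body.split(), dtype=float) if body.strip()
              else np.array([]))
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}")
    spec = GridSpec(
        n_rows=n_rows, n_cols=n_cols,
        x_min=float(header["xllcorner"]), y_min=float(header["yllcorner"]),
        cell_size=float(header["cellsize"]), nodata=nodata,
    )
    return RasterLayer(spec, name or path.stem, values.reshape(n_rows, n_cols))


def _is_number_row(line: str) -> bool:
    tok = line.split()
    if not tok:
        return False
    try:
        float(tok[0])
    except ValueError:
        return False
    # header lines are "KEY value" pairs; a data row starts with a number
    return len(tok) != 2 or _is_float(tok[1])


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_esri_ascii(layer: RasterLayer, path, full_precision: bool = False) -> None:
    spec = layer.spec
    fmt = "%.17g" if full_precision else "%.6g"
    vals = np.where(layer.mask, layer.values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {spec.n_cols}\n")
        fh.write(f"NROWS {spec.n_rows}\n")
        fh.write(f"XLLCORNER {spec.x_min!r}\n")
        fh.write(f"YLLCORNER {spec.y_min!r}\n")
        fh.write(f"CELLSIZE {spec.cell_size!r}\n")
        fh.write(f"NODATA_VALUE {spec.nodata!r}\n")
        np.savetxt(fh, vals, fmt=fmt)


# GeoTIFF tag ids (GeoTIFF 1.1 / GDAL conventions)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113
# minimal WGS84 geographic key directory
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 2048, 0, 1, 4326, 1025, 0, 1, 2)


def write_geotiff(layer: RasterLayer, path) -> None:
    import tifffile

    spec = layer.spec
    vals = np.where(layer.mask, layer.values, spec.nodata).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_min, spec.y_max, 0.0)),
        (_TAG_GEOKEYS, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_TAG_GDAL_NODATA, "s", 0, str(spec.nodata)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path, name: str | None = None) -> RasterLayer:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing georeferencing tags "
                         "(ModelPixelScale/ModelTiepoint)")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    if abs(sx - sy) > 1e-12:
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) not supported")
    tie = tags[_TAG_TIEPOINT]
    x_min, y_max = tie[3], tie[4]
    nodata = float(tags.get(_TAG_GDAL_NODATA, "-9999"))
    n_rows, n_cols = vals.shape
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, x_min=x_min,
                    y_min=y_max - n_rows * sy, cell_size=sx, nodata=nodata)
    return RasterLayer(spec, name or path.stem, vals)


def read_raster(path, dialect: str | None = None, name: str | None = None) -> RasterLayer:
    """Read a raster, dispatching on dialect ('geotiff' or 'esri_ascii')."""
    path = Path(path)
    if dialect is None:
        dialect = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "esri_ascii"
    if dialect == "geotiff":
        return read_geotiff(path, name)
    if dialect == "esri_ascii":
        return read_esri_ascii(path, name)
    raise ValueError(f"unknown raster dialect {dialect!r}")


def write_raster(layer: RasterLayer, path, dialect: str | None = None,
                 full_precision: bool = False) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "esri_ascii"
    if dialect == "geotiff":
        write_geotiff(layer, path)
    elif dialect == "esri_ascii":
        write_esri_ascii(layer, path, full_precision=full_precision)
    else:
        raise ValueError(f"unknown raster dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Resampling, area math, stack alignment

def resample_to(layer: RasterLayer, target: GridSpec, method: str = "nearest") -> RasterLayer:
    """Resample a layer onto a target grid by nearest-neighbour or bilinear.

    Bilinear interpolates between source cell centers, never overshooting the
    source min/max; any contribution from a nodata source cell makes the
    output cell nodata.
    """
    src = layer.spec
    if (target.x_min >= src.x_max or target.x_max <= src.x_min
            or target.y_min >= src.y_max or target.y_max <= src.y_min):
        raise ValueError("target grid does not overlap the source extent")
    if method == "nearest" and src.same_geometry(target):
        return RasterLayer(target, layer.name, layer.values.copy())

    lon = target.lon_centers()
    lat = target.lat_centers()
    lon2d, lat2d = np.meshgrid(lon, lat)
    if method == "nearest":
        row, col = src.cell_of(lon2d.ravel(), lat2d.ravel())
        out = np.full(row.shape, target.nodata)
        ok = row >= 0
        out[ok] = layer.values[row[ok], col[ok]]
        out[ok & (out == src.nodata)] = target.nodata
        return RasterLayer(target, layer.name, out.reshape(target.n_rows, target.n_cols))
    if method != "bilinear":
        raise ValueError(f"unknown resampling method {method!r}")

    # fractional index of each target center in source-center coordinates
    fx = (lon2d - (src.x_min + 0.5 * src.cell_size)) / src.cell_size
    fy = ((src.y_max - 0.5 * src.cell_size) - lat2d) / src.cell_size
    x0 = np.clip(np.floor(fx).astype(int), 0, src.n_cols - 1)
    y0 = np.clip(np.floor(fy).astype(int), 0, src.n_rows - 1)
    x1 = np.clip(x0 + 1, 0, src.n_cols - 1)
    y1 = np.clip(y0 + 1, 0, src.n_rows - 1)
    wx = np.clip(fx - x0, 0.0, 1.0)
    wy = np.clip(fy - y0, 0.0, 1.0)
    v = layer.values
    m = layer.mask
    corners = (v[y0, x0], v[y0, x1], v[y1, x0], v[y1, x1])
    weights = ((1 - wx) * (1 - wy), wx * (1 - wy), (1 - wx) * wy, wx * wy)
    out = sum(c * w for c, w in zip(corners, weights))
    valid = m[y0, x0] & m[y0, x1] & m[y1, x0] & m[y1, x1]
    out = np.where(valid, out, target.nodata)
    return RasterLayer(target, layer.name, out)


def cell_areas(spec: GridSpec) -> RasterLayer:
    """Per-cell spherical surface area in km².

    area = R² · Δλ · (sin φ_top − sin φ_bottom) with R = 6371 km.
    """
    dlon = np.radians(spec.cell_size)
    lat_top = np.radians(spec.y_max - np.arange(spec.n_rows) * spec.cell_size)
    lat_bot = np.radians(spec.y_max - (np.arange(spec.n_rows) + 1) * spec.cell_size)
    band = EARTH_RADIUS_KM ** 2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(band[:, None], spec.n_cols, axis=1)
    return RasterLayer(spec, "cell_area_km2", values)


def align_stack(layers: list[RasterLayer], target: GridSpec,
                method: str = "bilinear") -> RasterStack:
    """Resample layers onto one grid and unify their nodata masks."""
    names = [l.name for l in layers]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate layer names: {names}")
    resampled = []
    for l in layers:
        use = "nearest" if l.spec.same_geometry(target) else method
        resampled.append(resample_to(l, target, method=use))
    shared = resampled[0].mask
    for l in resampled[1:]:
        shared &= l.mask
    unified = [
        RasterLayer(target, l.name, np.where(shared, l.values, target.nodata))
        for l in resampled
    ]
    return RasterStack(unified)
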