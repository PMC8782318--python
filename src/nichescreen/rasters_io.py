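"""Gridded predictor layers, occurrence files and spatial sampling.

Predictor collections are directories of single-band rasters, one layer per
environmental variable, all on a common geographic grid.  Two on-disk
dialects are supported: ESRI ASCII grids (``.asc``) and single-band float
GeoTIFFs (``.tif``/``.tiff``).  Occurrences are plain CSV files with
``species,longitude,latitude`` columns.

Coordinates are geographic degrees.  A coordinate is mapped to the grid cell
that contains it, with cells half-open on their top and right edges, which
matches the lower-left-corner convention of ESRI ASCII headers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean Earth radius in km (IUGG), used for great-circle distances.
EARTH_RADIUS_KM = 6371.0088

RASTER_SUFFIXES = (".asc", ".tif", ".tiff")


class RasterFormatError(ValueError):
    """Malformed raster file (bad header field, inconsistent dimensions)."""


class CapacityError(ValueError):
    """Not enough valid cells to satisfy a sampling request."""


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    ``x_origin``/``y_origin`` are the coordinates of the *lower-left corner*
    of the grid (ESRI ASCII convention); ``cell_size`` is in degrees.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_value: float = -9999.0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def compatible(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """True if the two grids share geometry (nodata value may differ)."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Center coordinates of cell (row, col); row 0 is the top row."""
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def locate(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell containing (x, y), or None if outside the grid extent."""
        if not (self.x_origin <= x < self.x_max and self.y_origin <= y < self.y_max):
            return None
        col = int((x - self.x_origin) / self.cell_size)
        row = self.n_rows - 1 - int((y - self.y_origin) / self.cell_size)
        # guard floating-point edge cases on the extreme boundaries
        col = min(max(col, 0), self.n_cols - 1)
        row = min(max(row, 0), self.n_rows - 1)
        return row, col


@dataclass
class Layer:
    """One named environmental variable on a grid, nodata-masked."""

    name: str
    grid: GridSpec
    values: np.ma.MaskedArray

    def __post_init__(self) -> None:
        vals = np.ma.masked_invalid(np.ma.asarray(self.values, dtype=float))
        if vals.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"layer {self.name!r}: values shape {vals.shape} does not match "
                f"grid ({self.grid.n_rows}, {self.grid.n_cols})"
            )
        self.values = vals

    @property
    def mask(self) -> np.ndarray:
        return np.ma.getmaskarray(self.values)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# ESRI ASCII grid dialect
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, name: str | None = None) -> Layer:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and re.fullmatch(r"[A-Za-z_]+", parts[0]):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: header field {key!r} has non-numeric value {parts[1]!r}"
                ) from exc
            idx += 1
        else:
            break
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"{path}: missing required header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )
    body = " ".join(lines[idx:])
    try:
        data = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell value in body") from exc
    if data.size != grid.n_rows * grid.n_cols:
        raise RasterFormatError(
            f"{path}: expected {grid.n_rows * grid.n_cols} values "
            f"(nrows×ncols), found {data.size}"
        )
    data = data.reshape(grid.n_rows, grid.n_cols)
    values = np.ma.masked_values(data, nodata, atol=0.0, rtol=1e-12)
    return Layer(name=name or path.stem, grid=grid, values=values)


def write_ascii_grid(layer: Layer, path: str | Path, precision: int = 6) -> None:
    path = Path(path)
    g = layer.grid
    filled = layer.values.filled(g.nodata_value)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_origin:.10g}\n")
        fh.write(f"yllcorner {g.y_origin:.10g}\n")
        fh.write(f"cellsize {g.cell_size:.10g}\n")
        fh.write(f"NODATA_value {g.nodata_value:.10g}\n")
        np.savetxt(fh, filled, fmt=f"%.{precision}g")


# ---------------------------------------------------------------------------
# GeoTIFF dialect (single band, float32) via tifffile
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


def read_geotiff(path: str | Path, name: str | None = None) -> Layer:
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        if data.ndim != 2:
            raise RasterFormatError(f"{path}: expected a single-band raster")
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise RasterFormatError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    if abs(sx - sy) > 1e-9:
        raise RasterFormatError(f"{path}: non-square cells ({sx} × {sy}) unsupported")
    tie = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint maps raster (0,0) (upper-left corner) to model space
    x_ul, y_ul = tie[3], tie[4]
    n_rows, n_cols = data.shape
    nodata = float(str(tags.get(_TAG_GDAL_NODATA, "-9999")).strip().split()[0])
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=x_ul,
        y_origin=y_ul - n_rows * sy,
        cell_size=sx,
        nodata_value=nodata,
        crs_tag=str(tags.get(_TAG_GEO_ASCII, "")).strip("|"),
    )
    values = np.ma.masked_values(data, nodata, atol=0.0, rtol=1e-12)
    return Layer(name=name or path.stem, grid=grid, values=values)


def write_geotiff(layer: Layer, path: str | Path) -> None:
    import tifffile

    g = layer.grid
    filled = layer.values.filled(g.nodata_value).astype(np.float32)
    cs = float(g.cell_size)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(g.x_origin), float(g.y_max), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{g.nodata_value:.10g}"),
    ]
    if g.crs_tag:
        extratags.append((_TAG_GEO_ASCII, "s", 0, g.crs_tag + "|"))
    tifffile.imwrite(path, filled, extratags=extratags)


def read_layer(path: str | Path, name: str | None = None) -> Layer:
    """Read a raster layer, dispatching on file suffix (.asc/.tif/.tiff)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return read_ascii_grid(path, name=name)
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path, name=name)
    raise RasterFormatError(f"{path}: unrecognized raster suffix {suffix!r}")


def write_layer(layer: Layer, path: str | Path, precision: int = 6) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        write_ascii_grid(layer, path, precision=precision)
    elif suffix in (".tif", ".tiff"):
        write_geotiff(layer, path)
    else:
        raise RasterFormatError(f"{path}: unrecognized raster suffix {suffix!r}")


# ---------------------------------------------------------------------------
# Predictor collections
# ---------------------------------------------------------------------------

class PredictorCollection:
    """A directory of co-registered raster layers, loaded lazily.

    The collection is the screening universe: N named variables sharing one
    grid.  Layers are read from disk on first access and cached.
    """

    def __init__(self, directory: str | Path, paths: dict[str, Path]):
        if len(paths) < 2:
            raise ValueError("a predictor collection needs at least 2 layers")
        self.directory = Path(directory)
        self._paths = dict(sorted(paths.items()))
        self._cache: dict[str, Layer] = {}
        self._grid: GridSpec | None = None

    @classmethod
    def from_directory(cls, directory: str | Path) -> "PredictorCollection":
        directory = Path(directory)
        paths = {
            p.stem: p
            for p in sorted(directory.iterdir())
            if p.suffix.lower() in RASTER_SUFFIXES
        }
        if not paths:
            raise FileNotFoundError(f"no raster layers found in {directory}")
        return cls(directory, paths)

    @property
    def names(self) -> list[str]:
        return list(self._paths)

    def __len__(self) -> int:
        return len(self._paths)

    def __contains__(self, name: str) -> bool:
        return name in self._paths

    @property
    def grid(self) -> GridSpec:
        if self._grid is None:
            self.layer(self.names[0])
        return self._grid  # type: ignore[return-value]

    def layer(self, name: str) -> Layer:
        if name not in self._paths:
            raise KeyError(f"unknown variable {name!r}; collection has {self.names}")
        if name not in self._cache:
            lyr = read_layer(self._paths[name], name=name)
            if self._grid is None:
                self._grid = lyr.grid
            elif not self._grid.compatible(lyr.grid):
                raise RasterFormatError(
                    f"layer {name!r} grid is not compatible with the collection grid"
                )
            self._cache[name] = lyr
        return self._cache[name]

    def valid_mask(self, variable_names: list[str] | None = None) -> np.ndarray:
        """Boolean grid mask of cells valid (non-nodata) in every named layer."""
        names = variable_names if variable_names is not None else self.names
        valid = np.ones((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for nm in names:
            valid &= ~self.layer(nm).mask
        return valid


def extract(
    collection: PredictorCollection,
    variable_names: list[str],
    coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract covariate values at coordinates.

    Returns ``(values, valid)`` where ``values`` has one row per coordinate
    and one column per requested variable, and ``valid`` flags rows usable
    downstream.  A row is flagged invalid if the coordinate falls outside
    the grid or on a nodata cell in *any* requested layer; invalid entries
    are NaN.  The number of flagged rows is logged.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    grid = collection.grid
    n = coords.shape[0]
    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    inside = np.ones(n, dtype=bool)
    for i, (x, y) in enumerate(coords):
        loc = grid.locate(x, y)
        if loc is None:
            inside[i] = False
            rows[i] = cols[i] = 0
        else:
            rows[i], cols[i] = loc
    values = np.full((n, len(variable_names)), np.nan)
    valid = inside.copy()
    for j, nm in enumerate(variable_names):
        lyr = collection.layer(nm)
        vals = lyr.values.filled(np.nan)[rows, cols]
        masked = lyr.mask[rows, cols]
        values[:, j] = np.where(inside & ~masked, vals, np.nan)
        valid &= ~masked
    n_flagged = int((~valid).sum())
    if n_flagged:
        logger.info(
            "extract: %d/%d coordinates flagged (outside extent or nodata in %s)",
            n_flagged, n, variable_names,
        )
    return values, valid


def sample_background(
    collection: PredictorCollection, n_bg: int, seed: int
) -> np.ndarray:
    """Draw background points uniformly without replacement from valid cells.

    Returns an ``(n_bg, 2)`` array of cell-center (longitude, latitude)
    coordinates; only cells valid in every layer of the collection are
    eligible.  Deterministic under ``seed``.
    """
    valid = collection.valid_mask()
    flat = np.flatnonzero(valid.ravel())
    if flat.size < n_bg:
        raise CapacityError(
            f"requested {n_bg} background points but only {flat.size} valid cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n_bg, replace=False)
    grid = collection.grid
    rr, cc = np.divmod(chosen, grid.n_cols)
    xs = grid.x_origin + (cc + 0.5) * grid.cell_size
    ys = grid.y_origin + (grid.n_rows - rr - 0.5) * grid.cell_size
    return np.column_stack([xs, ys])


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Presence coordinates for one species (longitude, latitude in degrees)."""

    species: str
    points: np.ndarray  # (n, 2)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a ``species,longitude,latitude`` CSV; duplicates removed, logged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence file not found: {path}")
    df = pd.read_csv(path)
    required = {"species", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    extra = set(df.columns) - required
    notes = []
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, sorted(extra))
        notes.append(f"ignored columns: {sorted(extra)}")
    species = str(df["species"].iloc[0]) if len(df) else ""
    before = len(df)
    df = df.drop_duplicates(subset=["longitude", "latitude"])
    if len(df) < before:
        logger.info("%s: removed %d duplicate coordinate pairs", path, before - len(df))
        notes.append(f"removed {before - len(df)} duplicates")
    return OccurrenceSet(
        species=species,
        points=df[["longitude", "latitude"]].to_numpy(dtype=float),
        notes=notes,
    )


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "species": occ.species,
            "longitude": occ.points[:, 0],
            "latitude": occ.points[:, 1],
        }
    )
    df.to_csv(path, index=False)


def haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between rows of a and rows of b.

    Broadcasts to an ``(len(a), len(b))`` matrix.
    """
    a = np.deg2rad(np.atleast_2d(a))
    b = np.deg2rad(np.atleast_2d(b))
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def thin(occ: OccurrenceSet, buffer_km: float, seed: int) -> OccurrenceSet:
    """Spatially thin occurrences to pairwise distances ≥ ``buffer_km``.

    Greedy randomized retention: points are visited in a seeded random
    order and kept iff at least ``buffer_km`` (great-circle) from every
    already-kept point.  Exact coordinate duplicates are removed first.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    if len(occ) == 0:
        logger.warning("thin: empty occurrence set")
        return OccurrenceSet(occ.species, np.empty((0, 2)), notes=list(occ.notes))
    pts, idx = np.unique(occ.points, axis=0, return_index=True)
    if len(pts) < len(occ):
        logger.info("thin: removed %d duplicate points", len(occ) - len(pts))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(pts[i : i + 1], pts[kept])
        if float(d.min()) >= buffer_km:
            kept.append(i)
    kept_pts = pts[sorted(kept)]
    logger.info("thin: kept %d/%d points at buffer %.1f km", len(kept), len(occ), buffer_km)
    return OccurrenceSet(
        species=occ.species,
        points=kept_pts,
        notes=list(occ.notes) + [f"thinned to {len(kept)} points (buffer {buffer_km} km)"],
    )
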