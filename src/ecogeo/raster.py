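"""Co-registered environmental raster stacks and occurrence tables.

Grids are geographic (WGS84 lon/lat decimal degrees), cell-centre
registered, stored row-major with row 0 at the northern edge (the ESRI
ASCII grid convention).  Cell membership uses half-open intervals closed
at the lower/left edge, so every in-extent point belongs to exactly one
cell.  Rasters are read and written as ESRI ASCII grids (a plain-text
format: six-line header, then rows of values, ``NODATA_value`` honoured;
NaN is always masked).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

NODATA_DEFAULT = -9999.0
_TOL = 1e-9  # co-registration tolerance, decimal degrees


class CoRegistrationError(ValueError):
    """Raised when a grid does not match the expected shape/transform."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks required columns."""


@dataclass(frozen=True)
class GridTransform:
    """Georeferencing of a regular lon/lat grid.

    ``lon_min``/``lat_min`` are the outer (lower-left) corner of the grid,
    ``cellsize`` the square cell edge in decimal degrees.
    """

    lon_min: float
    lat_min: float
    cellsize: float

    def __post_init__(self):
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")

    def matches(self, other: "GridTransform", tol: float = _TOL) -> bool:
        return (
            abs(self.lon_min - other.lon_min) <= tol
            and abs(self.lat_min - other.lat_min) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )


@dataclass
class EnvStack:
    """Named, co-registered 2-D environmental layers with a shared mask.

    ``layers`` maps layer name to an (n_rows, n_cols) float array (row 0 =
    northernmost row); ``mask`` is True on valid cells and identical across
    layers; masked cells hold NaN.
    """

    layers: dict[str, np.ndarray]
    mask: np.ndarray
    transform: GridTransform
    crs_note: str = "WGS84 lon/lat decimal degrees, cell-centre registration"

    def __post_init__(self):
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1 or self.mask.shape not in shapes:
            raise CoRegistrationError("all layers and mask must share one shape")
        if min(self.mask.shape) < 1:
            raise ValueError("empty grid")
        self.mask = self.mask.astype(bool)
        for name in self.layers:
            arr = np.asarray(self.layers[name], dtype=float).copy()
            arr[~self.mask] = np.nan
            self.layers[name] = arr

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def lon_max(self) -> float:
        return self.transform.lon_min + self.shape[1] * self.transform.cellsize

    @property
    def lat_max(self) -> float:
        return self.transform.lat_min + self.shape[0] * self.transform.cellsize

    def lon_centers(self) -> np.ndarray:
        t = self.transform
        return t.lon_min + (np.arange(self.shape[1]) + 0.5) * t.cellsize

    def lat_centers(self) -> np.ndarray:
        """Cell-centre latitudes, row 0 (northern edge) first."""
        t = self.transform
        n = self.shape[0]
        return self.lat_max - (np.arange(n) + 0.5) * t.cellsize

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside.

        Half-open convention: a point on a cell's lower/left edge belongs to
        that cell; a point on the grid's outer upper/right edge is outside.
        """
        t = self.transform
        col = int(np.floor((lon - t.lon_min) / t.cellsize))
        row_s = int(np.floor((lat - t.lat_min) / t.cellsize))  # from south
        n_rows, n_cols = self.shape
        if not (0 <= col < n_cols and 0 <= row_s < n_rows):
            return None
        return n_rows - 1 - row_s, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return float(self.lon_centers()[col]), float(self.lat_centers()[row])

    def copy(self) -> "EnvStack":
        return EnvStack(
            {k: v.copy() for k, v in self.layers.items()},
            self.mask.copy(),
            self.transform,
            self.crs_note,
        )

    def values_table(self) -> pd.DataFrame:
        """All valid cells as a DataFrame, one column per layer."""
        idx = np.where(self.mask)
        return pd.DataFrame(
            {name: arr[idx] for name, arr in self.layers.items()}
        )


@dataclass
class OccurrenceSet:
    """Presence coordinates for one species (lon/lat decimal degrees)."""

    species: str
    points: np.ndarray  # (n, 2): lon, lat
    provenance: str = ""

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = np.empty((0, 2))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) lon/lat")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path, values: np.ndarray, mask: np.ndarray,
                     transform: GridTransform, nodata: float = NODATA_DEFAULT):
    """Write one layer as an ESRI ASCII grid (masked cells -> nodata)."""
    arr = np.asarray(values, dtype=float).copy()
    arr[~mask | ~np.isfinite(arr)] = nodata
    n_rows, n_cols = arr.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {transform.lon_min!r}\n"
        f"yllcorner {transform.lat_min!r}\n"
        f"cellsize {transform.cellsize!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in arr)
    Path(path).write_text(header + body + "\n")


def read_raster(path, expected_grid: EnvStack | None = None):
    """Read an ESRI ASCII grid -> (values, mask, transform).

    If ``expected_grid`` is given, the shape and transform must match it to
    within 1e-9 degrees, else a CoRegistrationError is raised.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster not found: {path}")
    text = path.read_text()
    header: dict[str, float] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        m = re.match(r"^\s*([A-Za-z_]+)\s+([-+0-9.eE]+)\s*$", lines[i])
        if not m:
            break
        header[m.group(1).lower()] = float(m.group(2))
        i += 1
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise IOError(f"malformed ESRI ASCII grid (missing {key}): {path}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value")
    vals = np.array(" ".join(lines[i:]).split(), dtype=float)
    if vals.size != n_rows * n_cols:
        raise IOError(f"expected {n_rows * n_cols} values, got {vals.size}: {path}")
    arr = vals.reshape(n_rows, n_cols)
    mask = np.isfinite(arr)
    if nodata is not None:
        mask &= arr != nodata
    arr = np.where(mask, arr, np.nan)
    transform = GridTransform(header["xllcorner"], header["yllcorner"],
                              header["cellsize"])
    if expected_grid is not None:
        if arr.shape != expected_grid.shape or not transform.matches(
                expected_grid.transform):
            raise CoRegistrationError(
                f"{path}: grid {arr.shape}/{transform} does not match expected "
                f"{expected_grid.shape}/{expected_grid.transform}")
    return arr, mask, transform


def write_stack(env: EnvStack, dirpath) -> list[Path]:
    """Write every layer of a stack as <dir>/<layer>.asc."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in env.layers.items():
        p = dirpath / f"{name}.asc"
        write_ascii_grid(p, arr, env.mask, env.transform)
        paths.append(p)
    return paths


def read_stack(dirpath, layer_names: list[str] | None = None) -> EnvStack:
    """Read <dir>/<layer>.asc files into a co-registered stack.

    The shared mask is the intersection of per-layer validity.
    """
    dirpath = Path(dirpath)
    if layer_names is None:
        layer_names = sorted(p.stem for p in dirpath.glob("*.asc"))
    if not layer_names:
        raise IOError(f"no .asc layers found in {dirpath}")
    layers, mask, transform, ref = {}, None, None, None
    for name in layer_names:
        arr, m, t = read_raster(dirpath / f"{name}.asc", ref)
        layers[name] = arr
        mask = m if mask is None else (mask & m)
        if ref is None:
            transform = t
            ref = EnvStack({name: arr}, m, t)
    return EnvStack(layers, mask, transform)


# ---------------------------------------------------------------------
# Occurrences


def read_occurrences(path) -> tuple[list[OccurrenceSet], int]:
    """Read a species,lon,lat[,source] CSV into per-species sets.

    Rows with missing/non-numeric coordinates are dropped and counted;
    byte-identical duplicate rows are collapsed.  Returns
    (sets ordered by first appearance, n_dropped).
    """
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"occurrence CSV must have columns {sorted(required)}; "
            f"got {list(df.columns)}")
    n0 = len(df)
    df = df.drop_duplicates()
    for c in ("lon", "lat"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=["lon", "lat"])
    n_dropped = n0 - len(df)
    sets = []
    for sp in df["species"].drop_duplicates():
        sub = df[df["species"] == sp]
        src = str(sub["source"].iloc[0]) if "source" in sub.columns else ""
        sets.append(OccurrenceSet(str(sp), sub[["lon", "lat"]].to_numpy(), src))
    return sets, n_dropped


def write_occurrences(sets: list[OccurrenceSet], path):
    rows = []
    for occ in sets:
        for lon, lat in occ.points:
            rows.append({"species": occ.species, "lon": lon, "lat": lat,
                         "source": occ.provenance})
    pd.DataFrame(rows, columns=["species", "lon", "lat", "source"]).to_csv(
        path, index=False)


def thin_to_grid(occ: OccurrenceSet, grid: EnvStack) -> OccurrenceSet:
    """Keep at most one record per grid cell (first in input order).

    Records outside the extent or on masked cells are removed.  Idempotent.
    """
    seen: set[tuple[int, int]] = set()
    kept = []
    for lon, lat in occ.points:
        cell = grid.cell_of(lon, lat)
        if cell is None or not grid.mask[cell]:
            continue
        if cell in seen:
            continue
        seen.add(cell)
        kept.append((lon, lat))
    pts = np.array(kept) if kept else np.empty((0, 2))
    return OccurrenceSet(occ.species, pts, occ.provenance)


def clip_window(env: EnvStack, lon_min: float, lon_max: float,
                lat_min: float, lat_max: float) -> EnvStack:
    """Sub-grid of cells whose centres fall in [lon_min, lon_max) x [lat_min, lat_max)."""
    lon_c, lat_c = env.lon_centers(), env.lat_centers()
    cols = np.where((lon_c >= lon_min) & (lon_c < lon_max))[0]
    rows = np.where((lat_c >= lat_min) & (lat_c < lat_max))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("clip window does not intersect the grid extent")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    t = env.transform
    new_t = GridTransform(
        t.lon_min + c0 * t.cellsize,
        t.lat_min + (env.shape[0] - r1) * t.cellsize,
        t.cellsize,
    )
    return EnvStack(
        {k: v[r0:r1, c0:c1].copy() for k, v in env.layers.items()},
        env.mask[r0:r1, c0:c1].copy(),
        new_t,
        env.crs_note,
    )


def extract_at_points(env: EnvStack, occ: OccurrenceSet
                      ) -> tuple[pd.DataFrame, int]:
    """Layer values at each point's containing cell.

    Returns (table with lon, lat and one column per layer; n_excluded for
    points outside the extent or on masked cells).  Raises if no point
    lands on a valid cell.
    """
    rows, n_excluded = [], 0
    for lon, lat in occ.points:
        cell = env.cell_of(lon, lat)
        if cell is None or not env.mask[cell]:
            n_excluded += 1
            continue
        rec = {"lon": lon, "lat": lat}
        rec.update({name: float(arr[cell]) for name, arr in env.layers.items()})
        rows.append(rec)
    if not rows:
        raise ValueError(f"all {len(occ)} points fall on masked/out-of-extent cells")
    return pd.DataFrame(rows), n_excluded
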