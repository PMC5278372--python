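"""Categorical raster data model and I/O.

The raster layer used throughout the package is a plain integer lattice with a
category schema (code -> name), a nodata code, and a simple grid geometry
(rows, columns, square cell size in metres, top-left origin). Two grids are
co-registered iff their geometries are identical; no resampling is performed
anywhere in the package.

Supported on-disk formats are single-band integer GeoTIFF (via tifffile, with
ModelPixelScale/ModelTiepoint/GDAL_NODATA tags) and ESRI ASCII Grid
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header, integer body).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategorySchema",
    "GridGeometry",
    "LandUseGrid",
    "TransitionMatrix",
    "DEFAULT_SCHEMA",
    "MERGED_SCHEMA",
    "MERGE_MAPPING",
    "read_raster",
    "write_raster",
    "reclassify",
    "class_areas",
    "crosstab",
    "trajectory_codes",
]

# GeoTIFF tag ids used for round-tripping geometry and nodata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GeometryMismatchError(ValueError):
    """Raised when an operation requires co-registered grids and gets none."""


class UnknownCodeError(ValueError):
    """Raised when a raster contains a value outside its category schema."""


@dataclass(frozen=True)
class CategorySchema:
    """Ordered category codes with labels and a distinct nodata code."""

    entries: tuple[tuple[int, str], ...]
    nodata_code: int = -9999

    def __post_init__(self) -> None:
        entries = tuple((int(c), str(n)) for c, n in self.entries)
        object.__setattr__(self, "entries", entries)
        codes = [c for c, _ in entries]
        names = [n for _, n in entries]
        if any(c <= 0 for c in codes):
            raise ValueError("category codes must be positive integers")
        if len(set(codes)) != len(codes):
            raise ValueError("category codes must be unique")
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        if self.nodata_code in codes:
            raise ValueError("nodata_code must differ from every category code")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    def name_of(self, code: int) -> str:
        for c, n in self.entries:
            if c == code:
                return n
        raise KeyError(f"code {code} not in schema")

    def code_of(self, name: str) -> int:
        for c, n in self.entries:
            if n == name:
                return c
        raise KeyError(f"name {name!r} not in schema")

    def __len__(self) -> int:
        return len(self.entries)


#: Seven-class schema used for the reconstruction.
DEFAULT_SCHEMA = CategorySchema(
    entries=(
        (1, "arable"),
        (2, "forest"),
        (3, "grassland"),
        (4, "water"),
        (5, "settlement"),
        (6, "wetland"),
        (7, "other_unused"),
    )
)

#: Six-class schema with wetland and other-unused merged into "unused",
#: used when comparing against sources that do not separate the two.
MERGED_SCHEMA = CategorySchema(
    entries=(
        (1, "arable"),
        (2, "forest"),
        (3, "grassland"),
        (4, "water"),
        (5, "settlement"),
        (6, "unused"),
    )
)

#: Mapping that derives the merged schema from the default one.
MERGE_MAPPING: dict[int, int] = {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6, 7: 6}


@dataclass(frozen=True)
class GridGeometry:
    """Square-cell grid geometry; row 0 is the northernmost row."""

    n_rows: int
    n_cols: int
    cell_size: float  # metres
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the top-left corner

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (90 m cell -> 0.81 ha)."""
        return self.cell_size**2 / 10000.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def __hash__(self) -> int:
        return hash((self.n_rows, self.n_cols))


@dataclass
class LandUseGrid:
    """2-D categorical raster: geometry + integer values + schema."""

    geometry: GridGeometry
    values: np.ndarray
    schema: CategorySchema

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(values == np.round(values)):
                raise UnknownCodeError("raster contains non-integer values")
            values = values.astype(np.int32)
        self.values = values.astype(np.int32, copy=False)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry {self.geometry.shape}"
            )
        self._validate_codes()

    def _validate_codes(self) -> None:
        allowed = set(self.schema.codes) | {self.schema.nodata_code}
        present = np.unique(self.values)
        bad = [int(v) for v in present if int(v) not in allowed]
        if bad:
            idx = np.argwhere(np.isin(self.values, bad))[0]
            raise UnknownCodeError(
                f"raster contains code(s) {bad} not in schema "
                f"(first offending cell: row {idx[0]}, col {idx[1]})"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.schema.nodata_code

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def class_mask(self, code: int) -> np.ndarray:
        return self.values == code

    def copy(self) -> "LandUseGrid":
        return LandUseGrid(self.geometry, self.values.copy(), self.schema)

    def equals(self, other: "LandUseGrid") -> bool:
        return self.geometry == other.geometry and np.array_equal(self.values, other.values)


def require_coregistered(*grids) -> None:
    """Raise GeometryMismatchError unless all inputs share one geometry."""
    geoms = [g.geometry for g in grids]
    for g in geoms[1:]:
        if g != geoms[0]:
            raise GeometryMismatchError(
                f"grids are not co-registered: {geoms[0]} vs {g}"
            )


@dataclass
class TransitionMatrix:
    """Class-by-class cross-tabulation between two dates.

    ``cells[i, j]`` holds the area (ha) or cell count that was class
    ``schema_initial.codes[i]`` at the first date and ``schema_final.codes[j]``
    at the second. The diagonal is persistence; off-diagonal mass is change.
    """

    schema_initial: CategorySchema
    schema_final: CategorySchema
    cells: np.ndarray
    unit: str = "ha"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (len(self.schema_initial), len(self.schema_final)):
            raise ValueError("matrix shape does not match schemas")
        if np.any(self.cells < 0):
            raise ValueError("transition matrix entries must be non-negative")
        if self.unit not in ("ha", "cells"):
            raise ValueError("unit must be 'ha' or 'cells'")

    @property
    def initial_totals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def final_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        n = min(self.cells.shape)
        return np.diag(self.cells)[:n]

    @property
    def gross_loss(self) -> np.ndarray:
        return self.initial_totals - np.diag(self.cells)

    @property
    def gross_gain(self) -> np.ndarray:
        return self.final_totals - np.diag(self.cells)

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells,
            index=list(self.schema_initial.names),
            columns=list(self.schema_final.names),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: CategorySchema, unit: str = "ha"):
        df = df.loc[list(schema.names), list(schema.names)]
        return cls(schema, schema, df.to_numpy(dtype=float), unit=unit)

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.schema_initial, self.schema_final, self.cells.copy(), self.unit)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, GridGeometry, int]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        m = re.match(r"^\s*([A-Za-z_]+)\s+(-?[\d.eE+]+)\s*$", line)
        if m and m.group(1).lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[m.group(1).lower()] = float(m.group(2))
            body_start += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header keyword {key}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    nodata = int(header.get("nodata_value", -9999))
    values = np.loadtxt(lines[body_start:], dtype=np.int64).reshape(n_rows, n_cols)
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    geom = GridGeometry(n_rows, n_cols, cell, origin=(xll, yll + n_rows * cell))
    return values, geom, nodata


def _write_ascii_grid(grid: LandUseGrid, path: Path) -> None:
    g = grid.geometry
    yll = g.origin[1] - g.n_rows * g.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin[0]:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {g.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.schema.nodata_code}\n")
        np.savetxt(fh, grid.values, fmt="%d")


def _read_geotiff(path: Path) -> tuple[np.ndarray, GridGeometry, int | None]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim == 3:  # single band stored with a trailing axis
            values = values[..., 0]
        tags = page.tags
        cell = 1.0
        origin = (0.0, 0.0)
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            if not np.isclose(sx, sy):
                raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
            cell = float(sx)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            # tiepoint (i, j, k, x, y, z) anchors raster (i, j) at model (x, y)
            origin = (float(tp[3] - tp[0] * cell), float(tp[4] + tp[1] * cell))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = int(float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 ")))
    n_rows, n_cols = values.shape
    geom = GridGeometry(n_rows, n_cols, cell, origin=origin)
    return values, geom, nodata


def _write_geotiff(grid: LandUseGrid, path: Path) -> None:
    import tifffile

    g = grid.geometry
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin[0], g.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.schema.nodata_code)),
    ]
    tifffile.imwrite(str(path), grid.values.astype(np.int32), extratags=extratags)


def read_raster(path, schema: CategorySchema) -> LandUseGrid:
    """Read a categorical raster (GeoTIFF or ESRI ASCII Grid).

    Every in-range value must be a schema code or the nodata code; anything
    else raises :class:`UnknownCodeError` naming the value and cell. A nodata
    value recorded in the file is remapped onto ``schema.nodata_code``.
    """
    path = Path(path)
    if path.suffix.lower() in (".asc", ".txt", ".grd"):
        values, geom, file_nodata = _read_ascii_grid(path)
    else:
        values, geom, file_nodata = _read_geotiff(path)
    values = np.asarray(values, dtype=np.int64)
    if file_nodata is not None and file_nodata != schema.nodata_code:
        values = np.where(values == file_nodata, schema.nodata_code, values)
    return LandUseGrid(geom, values, schema)


def write_raster(grid: LandUseGrid, path, format: str | None = None) -> None:
    """Write a grid as GeoTIFF or ESRI ASCII Grid (chosen by extension)."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "ascii" if path.suffix.lower() in (".asc", ".txt", ".grd") else "geotiff"
    if fmt not in ("ascii", "geotiff"):
        raise ValueError(f"unknown raster format {fmt!r}")
    if fmt == "ascii":
        _write_ascii_grid(grid, path)
    else:
        _write_geotiff(grid, path)


# ---------------------------------------------------------------------------
# Categorical primitives
# ---------------------------------------------------------------------------


def reclassify(
    grid: LandUseGrid,
    mapping: Mapping[int, int],
    out_schema: CategorySchema | None = None,
) -> LandUseGrid:
    """Apply a total code mapping per cell; nodata is preserved.

    ``mapping`` must cover every schema code. ``out_schema`` defaults to the
    input schema when the mapping is an endomorphism of it; pass e.g. the
    merged six-class schema when collapsing categories.
    """
    missing = [c for c in grid.schema.codes if c not in mapping]
    if missing:
        raise ValueError(f"mapping is not total: missing codes {missing}")
    if out_schema is None:
        out_schema = grid.schema
    lut_in = np.array(list(mapping.keys()), dtype=np.int64)
    lut_out = np.array([mapping[int(k)] for k in lut_in], dtype=np.int64)
    values = grid.values.copy().astype(np.int64)
    out = values.copy()
    for src, dst in zip(lut_in, lut_out):
        out[values == src] = dst
    out[values == grid.schema.nodata_code] = out_schema.nodata_code
    return LandUseGrid(grid.geometry, out, out_schema)


def class_areas(grid: LandUseGrid) -> pd.Series:
    """Per-class area in hectares: count(c) * cell_size^2 / 10000."""
    cell_area = grid.geometry.cell_area_ha
    counts = {
        name: int(np.count_nonzero(grid.values == code)) * cell_area
        for code, name in grid.schema.entries
    }
    return pd.Series(counts, name="area_ha")


def crosstab(grid_t1: LandUseGrid, grid_t2: LandUseGrid, unit: str = "ha") -> TransitionMatrix:
    """Cross-tabulate two co-registered grids into a transition matrix.

    A cell that is nodata in either grid is excluded. Row margins equal the
    class areas of the first grid over the jointly valid cells; column margins
    those of the second.
    """
    require_coregistered(grid_t1, grid_t2)
    valid = grid_t1.valid_mask & grid_t2.valid_mask
    codes1 = list(grid_t1.schema.codes)
    codes2 = list(grid_t2.schema.codes)
    pos1 = {c: i for i, c in enumerate(codes1)}
    pos2 = {c: j for j, c in enumerate(codes2)}
    v1 = grid_t1.values[valid]
    v2 = grid_t2.values[valid]
    i = np.array([pos1[int(v)] for v in np.ravel(v1)]) if v1.size else np.array([], int)
    j = np.array([pos2[int(v)] for v in np.ravel(v2)]) if v2.size else np.array([], int)
    flat = i * len(codes2) + j
    counts = np.bincount(flat, minlength=len(codes1) * len(codes2)).reshape(
        len(codes1), len(codes2)
    )
    scale = grid_t1.geometry.cell_area_ha if unit == "ha" else 1.0
    return TransitionMatrix(grid_t1.schema, grid_t2.schema, counts * scale, unit=unit)


def trajectory_codes(grids: Sequence[LandUseGrid]):
    """Label every cell by its ordered code sequence across >= 2 dates.

    Returns ``(trajectory_ids, trajectories, frequencies, unchanged_fraction)``:
    an integer grid of trajectory ids (-1 at nodata), the id -> "c1-c2-..."
    label mapping, a frequency table of cell counts per trajectory, and the
    per-class fraction of cells (classed by the first map) whose code never
    changes across the series.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise ValueError("trajectory analysis needs at least 2 grids")
    require_coregistered(*grids)
    schema = grids[0].schema
    valid = np.logical_and.reduce([g.valid_mask for g in grids])
    stack = np.stack([g.values for g in grids])  # (T, rows, cols)
    n_t = stack.shape[0]
    flat = stack.reshape(n_t, -1).T  # (cells, T)
    ids = np.full(flat.shape[0], -1, dtype=np.int64)
    valid_flat = valid.ravel()
    uniq, inv = np.unique(flat[valid_flat], axis=0, return_inverse=True)
    ids[valid_flat] = inv
    labels = {int(k): "-".join(str(int(c)) for c in row) for k, row in enumerate(uniq)}
    counts = np.bincount(inv, minlength=len(uniq))
    freq = pd.Series(
        {labels[k]: int(counts[k]) for k in range(len(uniq))}, name="n_cells"
    ).sort_values(ascending=False)
    unchanged = np.all(flat == flat[:, :1], axis=1) & valid_flat
    first = flat[:, 0]
    frac = {}
    for code, name in schema.entries:
        in_class = valid_flat & (first == code)
        n = int(in_class.sum())
        frac[name] = float(np.count_nonzero(unchanged & in_class)) / n if n else np.nan
    traj_grid = ids.reshape(valid.shape)
    return traj_grid, labels, freq, pd.Series(frac, name="unchanged_fraction")
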