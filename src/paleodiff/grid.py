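"""Grid geometry, ESRI ASCII raster I/O and the classed cost graph.

Cells live on a regular lon/lat grid and are addressed by a single 0-based
row-major linear index counted from the north-west corner. All geographic
lengths are great-circle (haversine) distances in km; no projection is
applied, because the model is meant to run at continental to hemispheric
extents where planar distances are wrong.

Landscape classes and their integer codes on disk:

    0 = SUITABLE         suitable habitat (cost factor fixed at 1)
    1 = UNSUITABLE_LAND  climatically unsuitable land
    2 = GLACIER          ice sheet
    3 = SEA              open or frozen sea

Crossing a non-suitable class multiplies the geographic length of an edge
by a cost factor >= 1, so least-cost paths bend around barriers without
ever being absolutely blocked.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import sparse

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "CostClass",
    "CostParams",
    "LandscapeGrid",
    "BinarySuitabilityRaster",
    "CostClassRaster",
    "SuitabilitySeries",
    "CostGraph",
    "great_circle_km",
    "build_cost_graph",
    "read_raster",
    "write_raster",
    "read_series_manifest",
    "write_series_manifest",
    "validate_series",
]


class CostClass(IntEnum):
    SUITABLE = 0
    UNSUITABLE_LAND = 1
    GLACIER = 2
    SEA = 3


@dataclass(frozen=True)
class LandscapeGrid:
    """Regular lon/lat grid; ``origin_lon/lat`` is the center of cell (0, 0)."""

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        lat_south = self.origin_lat - (self.n_rows - 1) * self.cell_size
        if not (-90.0 <= lat_south and self.origin_lat <= 90.0):
            raise ValueError("cell-center latitudes must lie in [-90, 90]")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, index: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of cell centers for linear indices."""
        index = np.asarray(index)
        row, col = np.divmod(index, self.n_cols)
        lon = self.origin_lon + col * self.cell_size
        lat = self.origin_lat - row * self.cell_size
        return lon, lat

    def all_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.cell_center(np.arange(self.n_cells))

    def index_of(self, row: int, col: int) -> int:
        return row * self.n_cols + col


@dataclass
class BinarySuitabilityRaster:
    grid: LandscapeGrid
    suitable: np.ndarray  # bool, shape (n_rows, n_cols)

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        if self.suitable.shape != self.grid.shape:
            raise ValueError("suitability shape does not match grid")

    def suitable_cells(self) -> np.ndarray:
        """Sorted linear indices of suitable cells."""
        return np.flatnonzero(self.suitable.ravel())


@dataclass
class CostClassRaster:
    grid: LandscapeGrid
    classes: np.ndarray  # int, shape (n_rows, n_cols), values in CostClass

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        if self.classes.shape != self.grid.shape:
            raise ValueError("class raster shape does not match grid")
        valid = {int(c) for c in CostClass}
        found = set(np.unique(self.classes).tolist())
        if not found <= valid:
            raise ValueError(f"unknown class codes: {sorted(found - valid)}")


@dataclass
class SuitabilitySeries:
    """Time-ordered (oldest -> newest) dynamic landscape on one shared grid."""

    steps: list[tuple[BinarySuitabilityRaster, CostClassRaster]]
    step_years: float = 100.0
    years_bp: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("series needs at least one step")
        if self.step_years <= 0:
            raise ValueError("step_years must be positive")

    @property
    def grid(self) -> LandscapeGrid:
        return self.steps[0][0].grid

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class CostParams:
    """Per-class traversal cost factors; suitable habitat is the unit cost."""

    unsuitable_land: float = 1.25
    glacier: float = 1.25
    sea: float = 1.25

    def __post_init__(self) -> None:
        for name in ("unsuitable_land", "glacier", "sea"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"cost factor {name} must be >= 1")

    def factor_lut(self) -> np.ndarray:
        """Lookup table indexed by CostClass code."""
        return np.array([1.0, self.unsuitable_land, self.glacier, self.sea])


@dataclass
class CostGraph:
    """Sparse symmetric graph over all grid cells with km-equivalent weights."""

    grid: LandscapeGrid
    adjacency: sparse.csr_matrix  # shape (n_cells, n_cells)
    params: CostParams = field(default_factory=CostParams)
    neighborhood: int = 8


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lon, lat) points in degrees."""
    lon1, lat1 = a
    lon2, lat2 = b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    return float(_haversine_km(np.array(lon1), np.array(lat1), np.array(lon2), np.array(lat2)))


def _haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


_NEIGHBOR_OFFSETS = {
    4: [(0, 1), (1, 0)],
    8: [(0, 1), (1, 0), (1, 1), (1, -1)],
}


def build_cost_graph(
    suitability: BinarySuitabilityRaster,
    classes: CostClassRaster,
    params: CostParams | None = None,
    neighborhood: int = 8,
) -> CostGraph:
    """Weighted grid graph: edge = great-circle length x mean endpoint factor.

    Every cell is a node regardless of class: non-suitable classes raise the
    cost of crossing but never block a path outright.
    """
    params = params or CostParams()
    if suitability.grid != classes.grid:
        raise ValueError("suitability and class rasters must share one grid")
    if neighborhood not in _NEIGHBOR_OFFSETS:
        raise ValueError("neighborhood must be 4 or 8")
    grid = classes.grid
    lut = params.factor_lut()
    factors = lut[classes.classes.ravel()]
    lon, lat = grid.all_centers()

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    nr, nc = grid.shape
    all_idx = np.arange(grid.n_cells).reshape(nr, nc)
    for dr, dc in _NEIGHBOR_OFFSETS[neighborhood]:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        src = all_idx[r0:r1, c0:c1].ravel()
        dst = all_idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        length = _haversine_km(lon[src], lat[src], lon[dst], lat[dst])
        w = length * 0.5 * (factors[src] + factors[dst])
        rows_i.append(src)
        rows_j.append(dst)
        weights.append(w)

    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(weights)
    adj = sparse.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(grid.n_cells, grid.n_cells),
    ).tocsr()
    return CostGraph(grid=grid, adjacency=adj, params=params, neighborhood=neighborhood)


# ---------------------------------------------------------------------------
# ESRI ASCII raster I/O

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner", "yllcenter", "cellsize", "nodata_value"}


def read_raster(path: str | Path, kind: str) -> BinarySuitabilityRaster | CostClassRaster:
    """Read an ESRI ASCII grid as a suitability or cost-class raster.

    NODATA cells map to unsuitable (kind="suitability") or UNSUITABLE_LAND
    (kind="cost_class"), keeping the cost graph fully connected.
    """
    if kind not in ("suitability", "cost_class"):
        raise ValueError("kind must be 'suitability' or 'cost_class'")
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if not data_lines and parts[0].lower() in _HEADER_KEYS and len(parts) == 2:
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcenter" in header:
        origin_lon = header["xllcenter"]
    elif "xllcorner" in header:
        origin_lon = header["xllcorner"] + cell / 2.0
    else:
        raise ValueError(f"{path}: missing xllcorner/xllcenter")
    if "yllcenter" in header:
        lat_south = header["yllcenter"]
    elif "yllcorner" in header:
        lat_south = header["yllcorner"] + cell / 2.0
    else:
        raise ValueError(f"{path}: missing yllcorner/yllcenter")
    origin_lat = lat_south + (n_rows - 1) * cell
    nodata = header.get("nodata_value")

    try:
        values = np.array([[float(v) for v in line.split()] for line in data_lines])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric raster value ({exc})") from exc
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data shape {values.shape} disagrees with header ({n_rows}, {n_cols})"
        )
    mask_nodata = np.zeros(values.shape, dtype=bool) if nodata is None else values == nodata

    grid = LandscapeGrid(n_rows, n_cols, origin_lon, origin_lat, cell)
    if kind == "suitability":
        suitable = (values != 0) & ~mask_nodata
        return BinarySuitabilityRaster(grid=grid, suitable=suitable)
    codes = values.astype(np.int8)
    codes[mask_nodata] = int(CostClass.UNSUITABLE_LAND)
    if not np.all(np.isin(codes, [int(c) for c in CostClass])):
        bad = sorted(set(np.unique(codes).tolist()) - {int(c) for c in CostClass})
        raise ValueError(f"{path}: unknown class codes {bad}")
    return CostClassRaster(grid=grid, classes=codes)


def write_raster(raster: BinarySuitabilityRaster | CostClassRaster, path: str | Path, nodata: int = -9999) -> None:
    """Write a raster as an ESRI ASCII grid (bit-exact integer round-trip)."""
    grid = raster.grid
    if isinstance(raster, BinarySuitabilityRaster):
        values = raster.suitable.astype(int)
    else:
        values = raster.classes.astype(int)
    lat_south = grid.origin_lat - (grid.n_rows - 1) * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon - grid.cell_size / 2.0:.10g}\n")
        fh.write(f"yllcorner {lat_south - grid.cell_size / 2.0:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def validate_series(series: SuitabilitySeries) -> list[str]:
    """Return a list of invariant violations (empty means the series is valid).

    Checked: one shared grid; suitability/cost-class agreement per cell
    (SUITABLE class iff suitable=True); warnings for fully unsuitable steps.
    """
    report: list[str] = []
    grid = series.grid
    for t, (suit, classes) in enumerate(series.steps):
        if suit.grid != grid:
            report.append(f"step {t}: suitability raster on a different grid")
            continue
        if classes.grid != grid:
            report.append(f"step {t}: cost-class raster on a different grid")
            continue
        is_suit_class = classes.classes == int(CostClass.SUITABLE)
        mismatch = np.flatnonzero(is_suit_class.ravel() != suit.suitable.ravel())
        for cell in mismatch[:20]:
            code = CostClass(int(classes.classes.ravel()[cell])).name
            report.append(
                f"step {t}: cell {int(cell)} suitability/class mismatch "
                f"(suitable={bool(suit.suitable.ravel()[cell])}, class={code})"
            )
        if len(mismatch) > 20:
            report.append(f"step {t}: ... {len(mismatch) - 20} further mismatching cells")
        if not suit.suitable.any():
            report.append(f"step {t}: warning: no suitable cells")
    return report


# ---------------------------------------------------------------------------
# Series manifest (CSV: step, years_bp, suitability path, cost_class path)


def write_series_manifest(
    series: SuitabilitySeries, directory: str | Path, prefix: str = "step"
) -> Path:
    """Write rasters plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "series_manifest.csv"
    n = len(series.steps)
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "years_bp", "suitability", "cost_class"])
        for t, (suit, classes) in enumerate(series.steps):
            if series.years_bp is not None:
                ybp = series.years_bp[t]
            else:
                ybp = (n - 1 - t) * series.step_years
            s_name = f"{prefix}{t:04d}_suitability.asc"
            c_name = f"{prefix}{t:04d}_costclass.asc"
            write_raster(suit, directory / s_name)
            write_raster(classes, directory / c_name)
            writer.writerow([t, f"{ybp:.10g}", s_name, c_name])
    return manifest


def read_series_manifest(path: str | Path, step_years: float = 100.0) -> SuitabilitySeries:
    path = Path(path)
    base = path.parent
    steps: list[tuple[BinarySuitabilityRaster, CostClassRaster]] = []
    years: list[float] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            suit = read_raster(base / row["suitability"], kind="suitability")
            classes = read_raster(base / row["cost_class"], kind="cost_class")
            steps.append((suit, classes))
            years.append(float(row["years_bp"]))
    return SuitabilitySeries(steps=steps, step_years=step_years, years_bp=years)
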