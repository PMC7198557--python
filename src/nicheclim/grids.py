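"""Gridded climate layers and their on-disk representation.

A :class:`ClimateStack` holds one 2-D array per bioclimatic variable on a
shared regular lon/lat grid, plus a boolean terrestrial mask.  Grids follow a
half-open cell convention: cell (i, j) covers
``[lat_min + i*cell, lat_min + (i+1)*cell) x [lon_min + j*cell, lon_min + (j+1)*cell)``
with row 0 at the southern edge.  Layers are stored as float arrays with NaN
on masked (non-terrestrial) cells.

Rasters are read and written as single-band ESRI ASCII grids (``.asc``), a
plain-text interchange format whose header carries the grid geometry and
nodata value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GridGeometry",
    "ClimateStack",
    "GridMap",
    "ScenarioSpec",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
]

_NODATA = -9999.0

RCP_CODES = ("RCP2.6", "RCP8.5")
GCM_CODES = ("CNRM-CM5", "GISS-E2-R", "MIROC-ESM-CHEM")


@dataclass(frozen=True)
class GridGeometry:
    """Regular geographic grid: row 0 = southernmost row, col 0 = westernmost."""

    n_rows: int
    n_cols: int
    cell_size: float
    lon_min: float = -180.0
    lat_min: float = -90.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a coordinate to (row, col), or None when outside the extent.

        Cells are half-open; a point exactly on the eastern/northern outer
        edge belongs to the last cell so the nominal extent is fully covered.
        """
        if not (self.lon_min <= lon <= self.lon_max):
            return None
        if not (self.lat_min <= lat <= self.lat_max):
            return None
        # on a global grid the antimeridian edge belongs to the lowest-index
        # cell (lon 180 == lon -180); otherwise outer edges fold inward
        if lon == self.lon_max and abs(self.lon_max - self.lon_min - 360.0) < 1e-9:
            j = 0
        else:
            j = min(int(math.floor((lon - self.lon_min) / self.cell_size)), self.n_cols - 1)
        i = min(int(math.floor((lat - self.lat_min) / self.cell_size)), self.n_rows - 1)
        return i, j

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.lon_min + (j + 0.5) * self.cell_size,
            self.lat_min + (i + 0.5) * self.cell_size,
        )

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row centre (used for cos-latitude area weights)."""
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.cell_size


@dataclass(frozen=True)
class ScenarioSpec:
    """Climate scenario identifier: current baseline or a future RCP x GCM."""

    period: str  # "current" | "future"
    rcp: str | None = None
    gcm: str | None = None

    def __post_init__(self) -> None:
        if self.period not in ("current", "future"):
            raise ValueError(f"period must be 'current' or 'future', got {self.period!r}")
        if self.period == "current":
            if self.rcp is not None or self.gcm is not None:
                raise ValueError("rcp/gcm may only be set for future scenarios")
        else:
            if self.rcp not in RCP_CODES:
                raise ValueError(f"rcp must be one of {RCP_CODES}, got {self.rcp!r}")
            if self.gcm not in GCM_CODES:
                raise ValueError(f"gcm must be one of {GCM_CODES}, got {self.gcm!r}")

    @property
    def tag(self) -> str:
        if self.period == "current":
            return "current"
        return f"{self.rcp}_{self.gcm}"


@dataclass
class ClimateStack:
    """Aligned bioclimatic layers sharing one grid geometry and land mask.

    ``layers`` maps variable codes (bio2, bio10, ...) to 2-D float arrays;
    temperature layers are in deg C, precipitation in mm.  ``mask`` is True on
    terrestrial cells; layer values are NaN wherever mask is False.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray]
    mask: np.ndarray
    period_tag: str = "current"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape must match grid geometry")
        for name, layer in self.layers.items():
            layer = np.asarray(layer, dtype=float)
            if layer.shape != self.geometry.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != grid {self.geometry.shape}")
            layer = layer.copy()
            layer[~self.mask] = np.nan
            self.layers[name] = layer

    @property
    def variables(self) -> list[str]:
        return sorted(self.layers)

    def env_table(self, rows: np.ndarray, cols: np.ndarray):
        """Per-cell environment values as a DataFrame (columns = variables)."""
        import pandas as pd

        data = {v: self.layers[v][rows, cols] for v in self.variables}
        return pd.DataFrame(data)

    def unmasked_cells(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.mask)

    def with_layers(self, layers: dict[str, np.ndarray], period_tag: str | None = None) -> "ClimateStack":
        return ClimateStack(
            geometry=self.geometry,
            layers={k: v.copy() for k, v in layers.items()},
            mask=self.mask.copy(),
            period_tag=self.period_tag if period_tag is None else period_tag,
        )


@dataclass
class GridMap:
    """A single scalar grid (favourability, binary class, ...) on a geometry."""

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray
    name: str = "map"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.geometry.shape or self.mask.shape != self.geometry.shape:
            raise ValueError("values/mask shape must match grid geometry")
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan


def write_ascii_grid(path: str | Path, values: np.ndarray, geometry: GridGeometry,
                     nodata: float = _NODATA) -> None:
    """Write one layer as an ESRI ASCII grid (text, rows north to south)."""
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.shape:
        raise ValueError("values shape must match geometry")
    out = values.copy()
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.lon_min!r}\n"
        f"yllcorner {geometry.lat_min!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w", encoding="ascii") as fh:
        fh.write(header)
        # ASCII grids store the northern row first; internal row 0 is southern
        np.savetxt(fh, out[::-1], fmt="%.17g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read an ESRI ASCII grid; returns (values, geometry, nodata).

    Nodata cells come back as NaN.
    """
    header: dict[str, float] = {}
    with open(path, "r", encoding="ascii") as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid {path}: missing header field {req!r}")
    geom = GridGeometry(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
    )
    if body.shape != geom.shape:
        raise ValueError(f"ASCII grid {path}: body shape {body.shape} != header {geom.shape}")
    values = body[::-1].copy()
    nodata = header.get("nodata_value", _NODATA)
    values[values == nodata] = np.nan
    return values, geom, nodata


def write_stack(stack: ClimateStack, directory: str | Path) -> list[Path]:
    """Write every layer of a stack as ``<var>.asc`` in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for var in stack.variables:
        p = directory / f"{var}.asc"
        write_ascii_grid(p, stack.layers[var], stack.geometry)
        paths.append(p)
    return paths


def read_stack(directory: str | Path, period_tag: str = "current") -> ClimateStack:
    """Read all ``*.asc`` layers in a directory into one aligned stack.

    The terrestrial mask is the intersection of finite cells across layers.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.asc"))
    if not files:
        raise FileNotFoundError(f"no .asc layers found in {directory}")
    layers: dict[str, np.ndarray] = {}
    geom: GridGeometry | None = None
    for f in files:
        values, g, _ = read_ascii_grid(f)
        if geom is None:
            geom = g
        elif g != geom:
            raise ValueError(f"layer {f.name} geometry {g} differs from {geom}")
        layers[f.stem] = values
    assert geom is not None
    mask = np.all([np.isfinite(v) for v in layers.values()], axis=0)
    return ClimateStack(geometry=geom, layers=layers, mask=mask, period_tag=period_tag)
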