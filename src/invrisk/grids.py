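"""Raster data model, ESRI ASCII grid I/O and geodesic cell areas.

All spatial stages of the pipeline share one lightweight raster
abstraction: a :class:`GridSpec` describing a regular lat-lon grid of
square cells, a named :class:`Layer` of values on that grid, and a
:class:`ClimateStack` of co-registered layers.  Internally row 0 is the
*northernmost* row, matching the ESRI ASCII file layout; nodata cells
are stored as NaN.

The normative on-disk format is the ESRI ASCII grid: a 6-line header
(NCOLS, NROWS, XLLCORNER, YLLCORNER, CELLSIZE, NODATA_value) followed by
whitespace-separated values, first row northernmost.  It is plain text
and diffable, which is why it is used for every raster this package
reads or writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0


class GridError(ValueError):
    """Malformed grid definition, header or value block."""


class GridMismatchError(GridError):
    """Two layers expected on the same grid have different specs."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid of square cells.

    ``x_min``/``y_min`` are the coordinates of the *outer corner* of the
    south-west cell (ESRI XLLCORNER/YLLCORNER convention); ``cell_size``
    is in decimal degrees and applies to both axes.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")
        if self.x_min < -180.0 - 1e-9 or self.x_max > 180.0 + 1e-9:
            raise GridError("grid exceeds [-180, 180] longitude")
        if self.y_min < -90.0 - 1e-9 or self.y_max > 90.0 + 1e-9:
            raise GridError("grid exceeds [-90, 90] latitude")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Half-open cell lookup: a point on an edge belongs to the cell
        with index ``floor((coord - origin) / cell_size)``.  Returns
        ``None`` for points outside the grid."""
        col = int(np.floor((lon - self.x_min) / self.cell_size))
        row_from_south = int(np.floor((lat - self.y_min) / self.cell_size))
        row = self.n_rows - 1 - row_from_south
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            return None
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.x_min + (col + 0.5) * self.cell_size
        lat = self.y_max - (row + 0.5) * self.cell_size
        return lon, lat

    def row_lat_edges(self, row: int) -> tuple[float, float]:
        """(bottom, top) latitude of a row band; row 0 is northernmost."""
        top = self.y_max - row * self.cell_size
        return top - self.cell_size, top

    def lat_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size


@dataclass
class Layer:
    """A named value grid; nodata cells are NaN in ``values``."""

    spec: GridSpec
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise GridError(
                f"layer {self.name!r}: values shape {self.values.shape} does not "
                f"match grid ({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self, name: str | None = None, values: np.ndarray | None = None) -> "Layer":
        return Layer(
            self.spec,
            self.name if name is None else name,
            self.values.copy() if values is None else values,
        )


@dataclass
class ClimateStack:
    """Ordered, co-registered layers (climate and optional soil covariates)."""

    spec: GridSpec
    layers: dict[str, Layer] = field(default_factory=dict)

    def add(self, layer: Layer) -> None:
        if layer.spec != self.spec:
            raise GridMismatchError(
                f"layer {layer.name!r} is on a different grid than the stack"
            )
        if layer.name in self.layers:
            raise GridError(f"duplicate layer name {layer.name!r}")
        self.layers[layer.name] = layer

    @classmethod
    def from_layers(cls, layers: Iterable[Layer]) -> "ClimateStack":
        layers = list(layers)
        if not layers:
            raise GridError("cannot build a stack from zero layers")
        stack = cls(spec=layers[0].spec)
        for lyr in layers:
            stack.add(lyr)
        return stack

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> Layer:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"stack has no layer named {name!r}") from None

    def __iter__(self) -> Iterator[Layer]:
        return iter(self.layers.values())

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers.keys())

    def joint_valid_mask(self) -> np.ndarray:
        """Cells valid in *every* layer (union of nodata masks removed)."""
        mask = np.ones((self.spec.n_rows, self.spec.n_cols), dtype=bool)
        for lyr in self.layers.values():
            mask &= lyr.valid_mask
        return mask

    def extract(
        self, rows: np.ndarray, cols: np.ndarray, variables: Sequence[str] | None = None
    ) -> np.ndarray:
        """Cells x variables matrix at the given cell indices (NaN where nodata)."""
        names = self.names if variables is None else list(variables)
        out = np.empty((len(rows), len(names)))
        for j, name in enumerate(names):
            out[:, j] = self[name].values[rows, cols]
        return out

    def subset(self, variables: Sequence[str]) -> "ClimateStack":
        return ClimateStack.from_layers([self[v] for v in variables])


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, name: str | None = None) -> Layer:
    """Read an ESRI ASCII grid into a Layer (nodata -> NaN).

    The layer name defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text().split("\n")
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridError(f"{path}: bad header value in line {line!r}") from exc
        else:
            data_start = i
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridError(f"{path}: missing header key(s): {', '.join(k.upper() for k in missing)}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    tokens = " ".join(text[data_start:]).split()
    try:
        flat = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise GridError(f"{path}: non-numeric value in data block") from exc
    if flat.size != n_rows * n_cols:
        raise GridError(
            f"{path}: expected {n_rows * n_cols} values "
            f"({n_rows} rows x {n_cols} cols), found {flat.size}"
        )
    values = flat.reshape(n_rows, n_cols)
    values[values == nodata] = np.nan
    return Layer(spec=spec, name=name or path.stem, values=values)


def write_ascii_grid(layer: Layer, path: str | Path, precision: int = 10) -> None:
    """Write a Layer as an ESRI ASCII grid; NaN cells become the nodata sentinel."""
    path = Path(path)
    spec = layer.spec
    vals = np.where(layer.valid_mask, layer.values, spec.nodata)
    fmt = f"%.{precision}g"
    lines = [
        f"NCOLS {spec.n_cols}",
        f"NROWS {spec.n_rows}",
        f"XLLCORNER {fmt % spec.x_min}",
        f"YLLCORNER {fmt % spec.y_min}",
        f"CELLSIZE {fmt % spec.cell_size}",
        f"NODATA_value {fmt % spec.nodata}",
    ]
    for row in vals:
        lines.append(" ".join(fmt % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_stack(directory: str | Path, pattern: str = "*.asc") -> ClimateStack:
    """Read every ASCII grid in a directory into one stack, named by file stem."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise GridError(f"no {pattern} rasters found in {directory}")
    return ClimateStack.from_layers([read_ascii_grid(p) for p in paths])


def cell_areas(spec: GridSpec) -> Layer:
    """Geodesic area of every cell in km^2 on a spherical Earth.

    For a cell spanning latitudes [phi_bot, phi_top] and longitude width
    d_lambda the spherical area is R^2 * d_lambda * (sin phi_top - sin phi_bot),
    identical across a longitude ring.
    """
    if spec.y_max > 90.0 + 1e-9 or spec.y_min < -90.0 - 1e-9:
        raise GridError("cells extend beyond +-90 degrees latitude")
    dlam = np.radians(spec.cell_size)
    tops = np.radians(spec.y_max - np.arange(spec.n_rows) * spec.cell_size)
    bots = tops - np.radians(spec.cell_size)
    band = EARTH_RADIUS_KM**2 * dlam * (np.sin(tops) - np.sin(bots))
    values = np.repeat(band[:, None], spec.n_cols, axis=1)
    return Layer(spec=spec, name="cell_area_km2", values=values)
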