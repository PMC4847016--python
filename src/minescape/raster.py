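"""Raster containers and ESRI ASCII grid I/O.

The canonical exchange format is the plain-text ESRI ASCII grid
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header followed
by row-major cell values, north row first).  Categorical land-use
rasters are int arrays of class codes; driving factors are float
rasters aligned cell-for-cell with the land-use grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

INT_NODATA = -9999
FLOAT_NODATA = -9999.0


@dataclass
class LandUseGrid:
    """Categorical land-use raster.

    data holds integer class codes; cells equal to ``nodata`` are
    outside the landscape.  cell_size is in meters, so the default
    100 m cell covers 1 hm².
    """

    data: np.ndarray
    cell_size: float = 100.0
    nodata: int = INT_NODATA
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("land-use raster must be 2-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area_hm2(self) -> float:
        return self.cell_size * self.cell_size / 10_000.0

    def class_counts(self) -> dict[int, int]:
        """Cell counts per class code over valid cells."""
        vals, counts = np.unique(self.data[self.valid_mask], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def class_areas(self) -> dict[int, float]:
        """Per-class areas in hm²."""
        a = self.cell_area_hm2
        return {c: n * a for c, n in self.class_counts().items()}

    def copy(self) -> "LandUseGrid":
        return replace(self, data=self.data.copy())


@dataclass
class DrivingFactorStack:
    """Stack of continuous driving-factor rasters keyed X1..Xn.

    data has shape (n_factors, nrows, ncols); all layers share the
    land-use grid's georeference and validity mask.
    """

    data: np.ndarray
    names: tuple[str, ...] = ()
    cell_size: float = 100.0
    nodata: float = FLOAT_NODATA
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("factor stack must be 3-D (factor, row, col)")
        if not self.names:
            self.names = tuple(f"X{i + 1}" for i in range(self.data.shape[0]))
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per factor layer required")

    @property
    def n_factors(self) -> int:
        return self.data.shape[0]

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def design_matrix(self, mask: np.ndarray) -> np.ndarray:
        """Cells × factors matrix over the given boolean mask."""
        return self.data[:, mask].T


def write_ascii_grid(
    array: np.ndarray,
    path: str | Path,
    cell_size: float = 100.0,
    nodata: float | int = INT_NODATA,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    Integer arrays are written as integers so that categorical grids
    round-trip bit-exactly; floats use repr precision.
    """
    array = np.asarray(array)
    if array.ndim != 2:
        raise ValueError("only 2-D arrays can be written as ASCII grids")
    is_int = np.issubdtype(array.dtype, np.integer)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {array.shape[1]}\n")
        fh.write(f"nrows {array.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {int(nodata) if is_int else repr(float(nodata))}\n")
        for row in array:
            if is_int:
                fh.write(" ".join(str(int(v)) for v in row))
            else:
                fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header dict).

    The array dtype is int if every value token parses as an integer,
    float otherwise.  Raises ValueError on malformed headers or ragged
    rows.
    """
    path = Path(path)
    header: dict[str, float] = {}
    required = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"]
    rows: list[list[str]] = []
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and len(header) < 6:
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() not in required:
            raise ValueError(f"malformed ASCII grid header line: {lines[i]!r}")
        header[parts[0].lower()] = float(parts[1])
        i += 1
    if sorted(header) != sorted(required):
        raise ValueError("incomplete ASCII grid header")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    for line in lines[i:]:
        if line.strip():
            rows.append(line.split())
    if len(rows) != nrows:
        raise ValueError(f"expected {nrows} data rows, found {len(rows)}")
    if any(len(r) != ncols for r in rows):
        raise ValueError("ragged rows in ASCII grid")
    flat = [tok for r in rows for tok in r]
    try:
        arr = np.array([int(t) for t in flat], dtype=np.int32)
    except ValueError:
        arr = np.array([float(t) for t in flat], dtype=float)
    meta = {
        "cell_size": header["cellsize"],
        "nodata": header["nodata_value"],
        "xllcorner": header["xllcorner"],
        "yllcorner": header["yllcorner"],
    }
    return arr.reshape(nrows, ncols), meta


def read_landuse(path: str | Path) -> LandUseGrid:
    arr, meta = read_ascii_grid(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("land-use grid must contain integer class codes")
    return LandUseGrid(
        arr,
        cell_size=meta["cell_size"],
        nodata=int(meta["nodata"]),
        xllcorner=meta["xllcorner"],
        yllcorner=meta["yllcorner"],
    )


def write_landuse(grid: LandUseGrid, path: str | Path) -> None:
    write_ascii_grid(
        grid.data, path, cell_size=grid.cell_size, nodata=grid.nodata,
        xllcorner=grid.xllcorner, yllcorner=grid.yllcorner,
    )


def write_factors(stack: DrivingFactorStack, directory: str | Path) -> list[Path]:
    """Write one .asc per factor layer into directory; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, layer in zip(stack.names, stack.data):
        p = directory / f"{name}.asc"
        write_ascii_grid(layer, p, cell_size=stack.cell_size, nodata=stack.nodata,
                         xllcorner=stack.xllcorner, yllcorner=stack.yllcorner)
        paths.append(p)
    return paths


def read_factors(paths: Iterable[str | Path]) -> DrivingFactorStack:
    layers, names, meta = [], [], None
    for p in paths:
        arr, m = read_ascii_grid(p)
        layers.append(arr.astype(float))
        names.append(Path(p).stem)
        if meta is None:
            meta = m
        elif arr.shape != layers[0].shape:
            raise ValueError("factor rasters are not aligned")
    if not layers:
        raise ValueError("no factor rasters given")
    return DrivingFactorStack(
        np.stack(layers), tuple(names), cell_size=meta["cell_size"],
        nodata=meta["nodata"], xllcorner=meta["xllcorner"], yllcorner=meta["yllcorner"],
    )
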