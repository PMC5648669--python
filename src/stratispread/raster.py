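"""Raster grids and Esri ASCII Grid I/O.

The :class:`RasterGrid` is the substrate for every map in the package:
survival layers, binary habitat landscapes, carrying-capacity maps and
population abundance states all share its geometry (cell size, lower-left
origin, nodata sentinel).  Row 0 of the in-memory array is the
*northernmost* row, matching the on-disk Esri ASCII convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid", "RasterFormatError", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class RasterFormatError(ValueError):
    """Raised when an Esri ASCII Grid file cannot be parsed."""


@dataclass
class RasterGrid:
    """2D numeric lattice with geometry.

    Parameters
    ----------
    values
        2D array; row 0 is the northernmost row.
    cell_size
        Edge length of a (square) cell in map units.
    origin
        (x, y) of the lower-left corner in map units.
    nodata
        Sentinel marking missing cells; never a valid probability or
        abundance.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def data_mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return ~np.isclose(self.values, self.nodata)

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this geometry but holding ``values``."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} != {self.shape}")
        return replace(self, values=values)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


# Type aliases used across modules; a SurvivalMap is a RasterGrid whose
# values lie in [0, 1].
SurvivalMap = RasterGrid


def read_ascii_grid(path) -> RasterGrid:
    """Read an Esri ASCII Grid.

    The header must contain NCOLS, NROWS, XLLCORNER, YLLCORNER and
    CELLSIZE (case-insensitive, any order); NODATA_VALUE is optional.
    Row 1 of the file is the northernmost row and stays row 0 in memory.
    """
    with open(path, "r", encoding="ascii") as fh:
        text = fh.read()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"non-numeric header value for {key!r}: {parts[1]!r}"
                ) from exc
            body_start = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"missing header field(s): {', '.join(missing)}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols <= 0 or nrows <= 0 or header["ncols"] != ncols or header["nrows"] != nrows:
        raise RasterFormatError("ncols/nrows must be positive integers")
    if header["cellsize"] <= 0:
        raise RasterFormatError("cellsize must be positive")
    body = "\n".join(lines[body_start:])
    try:
        values = np.loadtxt(io.StringIO(body), dtype=float, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"malformed data section: {exc}") from exc
    values = values.reshape(-1)
    if values.size != nrows * ncols:
        raise RasterFormatError(
            f"expected {nrows * ncols} values, found {values.size}"
        )
    return RasterGrid(
        values=values.reshape(nrows, ncols),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write ``grid`` as an Esri ASCII Grid (northernmost row first)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"ncols {grid.cols}\n")
        fh.write(f"nrows {grid.rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"nodata_value {grid.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")
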