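"""Deterministic toy rasters shared across test suites and examples.

Each fixture is a tiny, hand-checkable grid: a checkerboard (patch
counts differ between 4- and 8-neighbour rules), a two-patch map with
known inter-patch distance, and a three-class survival map with exact
class areas.  ``make_fixture`` writes them as Esri ASCII grids;
regeneration is bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .landscape import generate_fractal_surface, generate_survival_map
from .raster import RasterGrid, write_ascii_grid

__all__ = ["FIXTURES", "make_fixture", "fixture_grid"]


def _checkerboard() -> RasterGrid:
    v = np.indices((4, 4)).sum(axis=0) % 2
    return RasterGrid(v.astype(float))


def _two_patch() -> RasterGrid:
    v = np.zeros((5, 5))
    v[0, 0] = 1.0
    v[4, 4] = 1.0
    return RasterGrid(v)


def _three_class(seed: int = 7) -> RasterGrid:
    surface = generate_fractal_surface(9, 9, 0.5, seed)
    return generate_survival_map(surface, ((0.25, 0.05), (0.35, 0.3), (0.40, 0.8)))


FIXTURES = {
    "checkerboard": (
        "4x4 binary checkerboard; class 1 has NP=8 under the 4-neighbour "
        "rule and NP=1 under the 8-neighbour rule",
        lambda seed: _checkerboard(),
    ),
    "two_patch": (
        "5x5 map with single-cell patches at (0,0) and (4,4); minimum "
        "centre distance 4*sqrt(2) cells",
        lambda seed: _two_patch(),
    ),
    "three_class": (
        "9x9 survival map with 25% marginal (s=0.05), 35% less suitable "
        "(s=0.3) and 40% suitable (s=0.8) cells",
        _three_class,
    ),
}


def fixture_grid(name: str, seed: int = 7) -> RasterGrid:
    """Build a fixture grid in memory."""
    try:
        _, builder = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder(seed)


def make_fixture(name: str, out_dir, seed: int = 7) -> Path:
    """Write one fixture as ``<out_dir>/<name>.asc`` and return the path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.asc"
    write_ascii_grid(fixture_grid(name, seed), path)
    return path
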