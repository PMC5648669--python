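"""Neutral landscape generation.

Fractal continuous surfaces with a controllable Hurst exponent *H* are
generated by diamond-square midpoint displacement and turned into either
binary habitat landscapes with an exactly controlled habitat amount *P*
(quantile thresholding) or multi-class survival-probability maps.  Higher
*H* gives a smoother, more spatially aggregated surface and hence fewer,
larger habitat patches at a fixed *P*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raster import RasterGrid, SurvivalMap

__all__ = [
    "ContinuousSurface",
    "BinaryLandscape",
    "SuitabilityClass",
    "SuitabilityClassMap",
    "generate_fractal_surface",
    "threshold_to_binary",
    "classify_suitability",
    "generate_survival_map",
]


class SuitabilityClass(enum.IntEnum):
    """Three-way suitability partition of a survival layer.

    ``SUITABLE``: survival probability s > 0.5; ``LESS_SUITABLE``:
    0.1 <= s < 0.5 (s = 0.5 falls here as well, the upper bound being
    open on both neighbouring intervals); ``MARGINAL``: s < 0.1.
    """

    MARGINAL = 0
    LESS_SUITABLE = 1
    SUITABLE = 2


@dataclass
class ContinuousSurface:
    """Fractal surface rescaled to [0, 1], with its generating parameters."""

    grid: RasterGrid
    hurst: float
    seed: int


@dataclass
class BinaryLandscape:
    """Binary habitat map: 1 = suitable, 0 = unsuitable."""

    grid: RasterGrid
    proportion: float


@dataclass
class SuitabilityClassMap:
    """Categorical map holding :class:`SuitabilityClass` codes."""

    grid: RasterGrid


def _next_pow2_plus1(n: int) -> int:
    k = 0
    while 2**k + 1 < n:
        k += 1
    return 2**k + 1


def generate_fractal_surface(
    rows: int, cols: int, hurst: float, seed: int
) -> ContinuousSurface:
    """Generate a fractal surface by diamond-square midpoint displacement.

    The surface is built on the smallest (2^n + 1) x (2^n + 1) lattice
    covering the requested shape, cropped to ``(rows, cols)`` from the
    top-left corner, and min-max rescaled to [0, 1].  The per-level
    random displacement amplitude shrinks by 2^(-H) at each halving of
    the lattice spacing, so ``hurst`` controls spatial autocorrelation:
    H near 1 yields smooth, aggregated surfaces, H near 0 rough ones.

    Deterministic for a fixed ``(rows, cols, hurst, seed)``.
    """
    if not (isinstance(rows, (int, np.integer)) and isinstance(cols, (int, np.integer))):
        raise TypeError("rows and cols must be integers")
    if rows < 2 or cols < 2:
        raise ValueError(f"rows and cols must be >= 2, got ({rows}, {cols})")
    if not np.isfinite(hurst) or not (0.0 <= hurst <= 1.0):
        raise ValueError(f"hurst must be finite and in [0, 1], got {hurst}")

    size = _next_pow2_plus1(max(rows, cols))
    rng = np.random.default_rng(seed)
    z = np.zeros((size, size))
    z[0, 0], z[0, -1], z[-1, 0], z[-1, -1] = rng.normal(0.0, 1.0, 4)

    side = size - 1
    amp = 1.0
    while side >= 2:
        half = side // 2
        amp *= 2.0 ** (-hurst)
        # diamond step: centres of squares
        cr = np.arange(half, size, side)
        z[np.ix_(cr, cr)] = 0.25 * (
            z[np.ix_(cr - half, cr - half)]
            + z[np.ix_(cr - half, cr + half)]
            + z[np.ix_(cr + half, cr - half)]
            + z[np.ix_(cr + half, cr + half)]
        ) + rng.normal(0.0, amp, (cr.size, cr.size))
        # square step: edge midpoints, averaging in-grid diamond neighbours
        rr, cc = np.meshgrid(np.arange(0, size, half), np.arange(0, size, half),
                             indexing="ij")
        edge = (rr // half + cc // half) % 2 == 1
        er, ec = rr[edge], cc[edge]
        acc = np.zeros(er.size)
        cnt = np.zeros(er.size)
        for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
            nr, nc = er + dr, ec + dc
            ok = (nr >= 0) & (nr < size) & (nc >= 0) & (nc < size)
            acc[ok] += z[nr[ok], nc[ok]]
            cnt[ok] += 1
        z[er, ec] = acc / cnt + rng.normal(0.0, amp, er.size)
        side = half

    z = z[:rows, :cols]
    lo, hi = z.min(), z.max()
    if hi > lo:
        z = (z - lo) / (hi - lo)
    else:
        z = np.zeros_like(z)
    return ContinuousSurface(grid=RasterGrid(values=z), hurst=float(hurst),
                             seed=int(seed))


def threshold_to_binary(surface: ContinuousSurface, proportion: float) -> BinaryLandscape:
    """Threshold a surface so that exactly round(P * ncells) cells are suitable.

    The highest-valued cells become habitat; ties at the threshold are
    broken by row-major cell index, so the suitable-cell count is exact
    rather than an expectation — habitat amount P is a controlled
    quantity.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    values = surface.grid.values
    n = values.size
    k = int(round(proportion * n))
    binary = np.zeros(n, dtype=float)
    if k > 0:
        # stable sort on descending value: ties resolved by row-major index
        order = np.argsort(-values.ravel(), kind="stable")
        binary[order[:k]] = 1.0
    return BinaryLandscape(
        grid=surface.grid.like(binary.reshape(values.shape)),
        proportion=float(proportion),
    )


def classify_suitability(survival: SurvivalMap) -> SuitabilityClassMap:
    """Partition a survival layer into suitable / less suitable / marginal.

    suitable: s > 0.5; less suitable: 0.1 <= s < 0.5 (and s = 0.5);
    marginal: s < 0.1.
    """
    s = survival.values
    if np.any(~np.isfinite(s)) or s.min() < 0.0 or s.max() > 1.0:
        raise ValueError("survival probabilities must be finite and in [0, 1]")
    codes = np.full(s.shape, SuitabilityClass.LESS_SUITABLE, dtype=np.int64)
    codes[s < 0.1] = SuitabilityClass.MARGINAL
    codes[s > 0.5] = SuitabilityClass.SUITABLE
    return SuitabilityClassMap(grid=survival.like(codes))


def generate_survival_map(
    surface: ContinuousSurface,
    levels: Sequence[tuple[float, float]],
) -> SurvivalMap:
    """Assign survival probabilities to quantile bands of a surface.

    ``levels`` is a sequence of ``(quantile_mass, survival_probability)``
    pairs, listed from the lowest surface values upward; the masses must
    sum to 1.  Band boundaries are exact cell counts (round of the
    cumulative mass), with ties at a boundary resolved by row-major
    index, so each class's areal share is controlled exactly.  This is a
    synthetic stand-in for GIS-derived suitability layers and enables
    multi-class experiments without external data.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    masses = np.array([m for m, _ in levels], dtype=float)
    probs = np.array([p for _, p in levels], dtype=float)
    if np.any(masses < 0):
        raise ValueError("quantile masses must be non-negative")
    if abs(masses.sum() - 1.0) > 1e-9:
        raise ValueError(f"quantile masses must sum to 1, got {masses.sum()}")
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise ValueError("survival probabilities must be in [0, 1]")
    values = surface.grid.values
    n = values.size
    order = np.argsort(values.ravel(), kind="stable")  # ascending
    bounds = np.round(np.cumsum(masses) * n).astype(int)
    bounds[-1] = n  # guard against cumulative rounding drift
    out = np.empty(n, dtype=float)
    start = 0
    for stop, p in zip(bounds, probs):
        out[order[start:stop]] = p
        start = stop
    return surface.grid.like(out.reshape(values.shape))
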