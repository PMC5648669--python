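"""Stratified dispersal: local neighbourhood spread plus long-distance jumps.

Local spread is a short-range diffusion step: a fixed proportion of the
individuals in each occupied cell moves to the surrounding neighbourhood
(directions and radius configurable).  Long-distance dispersal is an
event process: each occupied cell generates a Poisson number of jump
events per step; each event travels a distance drawn from a fat-tailed
(half-Cauchy) or exponential kernel — or a weighted mixture — in a
direction drawn uniformly on [0, 2pi).  Events landing outside the grid
are lost (absorbing boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LocalDispersalSpec",
    "KernelComponent",
    "KernelSpec",
    "neighborhood_offsets",
    "local_spread",
    "sample_event_count",
    "sample_distances",
    "sample_event_displacement",
    "kernel_spread",
]

_DIRECTIONS = ("E", "N", "W", "S")


@dataclass
class LocalDispersalSpec:
    """Short-range neighbourhood movement.

    ``proportion`` of the individuals in an occupied cell leaves per
    step; ``shape`` enables movement east/north/west/south; ``range``
    is the Chebyshev radius of the neighbourhood in cells.  A diagonal
    neighbour is eligible only when both of its axis directions are
    enabled.  ``allocation='deterministic'`` splits migrants equally
    among eligible neighbours (exact mass conservation away from the
    boundary); ``'multinomial'`` draws an integer migrant count and
    allocates it multinomially with equal probabilities.
    """

    proportion: float = 0.2
    shape: tuple[str, ...] = ("E", "N", "W", "S")
    range: int = 1
    allocation: str = "deterministic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"proportion must be in [0, 1], got {self.proportion}")
        shape = tuple(d.upper() for d in self.shape)
        bad = [d for d in shape if d not in _DIRECTIONS]
        if bad or not shape:
            raise ValueError(f"shape must be a non-empty subset of {_DIRECTIONS}")
        self.shape = shape
        if self.range < 1:
            raise ValueError(f"range must be >= 1, got {self.range}")
        if self.allocation not in ("deterministic", "multinomial"):
            raise ValueError("allocation must be 'deterministic' or 'multinomial'")


def neighborhood_offsets(spec: LocalDispersalSpec) -> np.ndarray:
    """(k, 2) array of (drow, dcol) offsets eligible under ``spec``.

    Row offsets are negative toward the north (row 0 is the
    northernmost row).
    """
    dirs = set(spec.shape)
    offsets = []
    R = spec.range
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            if dr == 0 and dc == 0:
                continue
            if dr < 0 and "N" not in dirs:
                continue
            if dr > 0 and "S" not in dirs:
                continue
            if dc > 0 and "E" not in dirs:
                continue
            if dc < 0 and "W" not in dirs:
                continue
            offsets.append((dr, dc))
    return np.array(offsets, dtype=int)


def local_spread(
    state: np.ndarray,
    spec: LocalDispersalSpec,
    rng: np.random.Generator | None = None,
    mode: str = "abundance",
) -> np.ndarray:
    """One step of local neighbourhood spread.

    Abundance mode: ``proportion * N`` migrants leave each cell and are
    divided among the eligible neighbours (equally, or by a multinomial
    draw); mass is conserved except across the grid boundary, where
    migrants are absorbed.  Presence mode: each eligible neighbour of an
    occupied cell becomes occupied with probability ``proportion``.
    """
    if spec.proportion == 0.0:
        return state.copy()
    offsets = neighborhood_offsets(spec)
    k = len(offsets)
    rows, cols = state.shape

    if mode == "presence":
        if rng is None:
            raise ValueError("presence-mode local spread requires an rng")
        occ = state.astype(bool)
        out = occ.copy()
        rr, cc = np.nonzero(occ)
        if rr.size:
            hits = rng.random((rr.size, k)) < spec.proportion
            for j, (dr, dc) in enumerate(offsets):
                nr, nc = rr + dr, cc + dc
                ok = hits[:, j] & (nr >= 0) & (nr < rows) & (nc >= 0) & (nc < cols)
                out[nr[ok], nc[ok]] = True
        return out

    N = np.asarray(state, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundances must be non-negative")
    if spec.allocation == "deterministic":
        migrants = spec.proportion * N
        out = N - migrants
        share = migrants / k
        for dr, dc in offsets:
            src = share[
                max(0, -dr): rows - max(0, dr),
                max(0, -dc): cols - max(0, dc),
            ]
            out[
                max(0, dr): rows + min(0, dr),
                max(0, dc): cols + min(0, dc),
            ] += src
        return out

    if rng is None:
        raise ValueError("multinomial allocation requires an rng")
    m_real = spec.proportion * N.ravel()
    # stochastic rounding keeps the expected migrant mass exact
    m_int = np.floor(m_real).astype(np.int64)
    m_int += rng.random(m_int.size) < (m_real - m_int)
    out = N.ravel() - m_int.astype(float)
    src_idx = np.nonzero(m_int > 0)[0]
    if src_idx.size:
        draws = rng.multinomial(m_int[src_idx], np.full(k, 1.0 / k))
        rr, cc = np.divmod(src_idx, cols)
        flat_out = out
        for j, (dr, dc) in enumerate(offsets):
            nr, nc = rr + dr, cc + dc
            ok = (nr >= 0) & (nr < rows) & (nc >= 0) & (nc < cols)
            np.add.at(flat_out, nr[ok] * cols + nc[ok], draws[ok, j].astype(float))
    return out.reshape(rows, cols)


@dataclass
class KernelComponent:
    """One mixture component of the long-distance kernel.

    ``cauchy``: distance = |draw from Cauchy(x0, f)| with location
    ``x0`` and scale ``scale`` (f), both in map units; when x0 >> f the
    median distance is close to x0.  ``exponential``: distance drawn
    with the given ``scale`` (mean), in map units.
    """

    weight: float = 1.0
    family: str = "cauchy"
    x0: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("cauchy", "exponential"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")
        if not self.scale > 0:
            raise ValueError(f"kernel scale must be positive, got {self.scale}")


@dataclass
class KernelSpec:
    """Long-distance dispersal events from occupied cells.

    ``lambda_events`` is the Poisson mean number of jump events per
    occupied cell per step.  ``components`` is a mixture of distance
    distributions (weights are normalised to sum to 1).  In abundance
    mode each event deposits ``propagule_size`` individuals at the
    destination; if ``propagule_fraction`` is set instead, an event
    carries that fraction of the source cell's current abundance, so
    propagule pressure scales with how large the source population has
    grown.  Propagules are colonists and are not debited from the
    source cell.
    """

    lambda_events: float = 1.0
    components: tuple[KernelComponent, ...] = field(
        default_factory=lambda: (KernelComponent(),)
    )
    propagule_size: float = 1.0
    propagule_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_events < 0:
            raise ValueError(f"lambda_events must be >= 0, got {self.lambda_events}")
        if self.propagule_fraction is not None and not (0 < self.propagule_fraction <= 1):
            raise ValueError("propagule_fraction must be in (0, 1]")
        self.components = tuple(self.components)
        if not self.components:
            raise ValueError("kernel needs at least one component")
        total = sum(c.weight for c in self.components)
        if not total > 0:
            raise ValueError("component weights must sum to a positive value")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([c.weight for c in self.components], dtype=float)
        return w / w.sum()


def sample_event_count(lambda_events: float, rng: np.random.Generator, size=None):
    """Poisson draw(s) of the number of long-distance events."""
    if lambda_events < 0:
        raise ValueError("lambda_events must be >= 0")
    return rng.poisson(lambda_events, size)


def sample_distances(spec: KernelSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw jump distances (map units) from the kernel mixture."""
    comps = spec.components
    if len(comps) == 1:
        which = np.zeros(size, dtype=int)
    else:
        which = rng.choice(len(comps), size=size, p=spec.weights)
    d = np.empty(size, dtype=float)
    for i, comp in enumerate(comps):
        idx = np.nonzero(which == i)[0]
        if idx.size == 0:
            continue
        if comp.family == "cauchy":
            d[idx] = np.abs(comp.x0 + comp.scale * rng.standard_cauchy(idx.size))
        else:
            d[idx] = rng.exponential(comp.scale, idx.size)
    return d


def sample_event_displacement(spec: KernelSpec, rng: np.random.Generator, size=None):
    """Draw (dx, dy) displacement(s) in map units: kernel distance at a
    uniform angle on [0, 2pi)."""
    n = 1 if size is None else int(size)
    d = sample_distances(spec, rng, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dx, dy = d * np.cos(theta), d * np.sin(theta)
    if size is None:
        return float(dx[0]), float(dy[0])
    return dx, dy


def kernel_spread(
    state: np.ndarray,
    spec: KernelSpec,
    rng: np.random.Generator,
    cell_size: float = 1.0,
    mode: str = "abundance",
    occupancy_threshold: float = 1.0,
) -> np.ndarray:
    """One step of long-distance dispersal.

    Each occupied cell (abundance >= ``occupancy_threshold``, or any
    occupied cell in presence mode) generates a Poisson(lambda) number
    of events; each lands in the cell containing the source centre plus
    the sampled displacement.  Off-grid events are lost.  Destinations
    become occupied (presence) or gain ``propagule_size`` individuals
    (abundance); sources are not debited.
    """
    rows, cols = state.shape
    if mode == "presence":
        occ = state.astype(bool)
        src_r, src_c = np.nonzero(occ)
        out = occ.copy()
    else:
        N = np.asarray(state, dtype=float)
        src_r, src_c = np.nonzero(N >= occupancy_threshold)
        out = N.copy()
    if src_r.size == 0 or spec.lambda_events == 0:
        return out

    counts = rng.poisson(spec.lambda_events, src_r.size)
    total = int(counts.sum())
    if total == 0:
        return out
    er = np.repeat(src_r, counts)
    ec = np.repeat(src_c, counts)
    dx, dy = sample_event_displacement(spec, rng, size=total)
    # +y is north, i.e. decreasing row index
    dest_c = np.floor(ec + 0.5 + dx / cell_size).astype(np.int64)
    dest_r = np.floor(er + 0.5 - dy / cell_size).astype(np.int64)
    ok = (dest_r >= 0) & (dest_r < rows) & (dest_c >= 0) & (dest_c < cols)
    if mode == "presence":
        out[dest_r[ok], dest_c[ok]] = True
    elif spec.propagule_fraction is not None:
        carried = np.repeat(spec.propagule_fraction * N[src_r, src_c], counts)
        np.add.at(out, (dest_r[ok], dest_c[ok]), carried[ok])
    else:
        np.add.at(out, (dest_r[ok], dest_c[ok]), spec.propagule_size)
    return out
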