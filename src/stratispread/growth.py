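"""Per-cell population growth maps.

Each family advances a cell's abundance one time step:

* ``logistic``        N' = N + r N (1 - N/K)
* ``beverton_holt``   N' = e^r N / (1 + (e^r - 1) N / K)
* ``ricker``          N' = N exp(r (1 - N/K))
* ``allee_logistic``  N' = phi_1(N), the time-1 flow of the strong-Allee
  logistic ODE dN/dt = r N (1 - N/K) (N/A - 1)

r is the intrinsic rate of increase per time step and K the carrying
capacity (individuals per cell; a scalar or a per-cell raster).  The
Beverton-Holt map is parameterised through the finite rate e^r so that r
has the same meaning across families.

The Allee map is integrated within the step rather than applied as a
one-step Euler difference because the Euler form
N + rN(1 - N/K)(N/A - 1) is violently unstable at the carrying capacity
whenever r > 2A/(K - A) (for A << K that is essentially any r of
interest): it overshoots K and collapses to zero instead of settling
there.  The integrated flow keeps the textbook fixed-point structure
{0, A, K} — A an unstable threshold below which populations decline, K
globally attracting from above A — for every r > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["GrowthSpec", "grow", "GROWTH_FAMILIES"]

GROWTH_FAMILIES = ("logistic", "beverton_holt", "ricker", "allee_logistic")


@dataclass
class GrowthSpec:
    """Growth family and parameters.

    ``K`` may be a scalar or a per-cell array (resolved against the
    simulation landscape by the engine).  ``stochastic=True`` replaces
    the deterministic update with a Poisson draw around it, adding
    demographic noise.
    """

    family: str = "logistic"
    r: float = 0.5
    K: float | np.ndarray = 100.0
    A: float | None = None
    stochastic: bool = False

    def __post_init__(self) -> None:
        if self.family not in GROWTH_FAMILIES:
            raise ValueError(
                f"unknown growth family {self.family!r}; choose from {GROWTH_FAMILIES}"
            )
        if not np.isfinite(self.r) or self.r <= -1:
            raise ValueError(f"r must be finite and > -1, got {self.r}")
        if self.family == "allee_logistic":
            if self.A is None:
                raise ValueError("allee_logistic requires an Allee threshold A")
            if not self.A > 0:
                raise ValueError(f"Allee threshold A must be positive, got {self.A}")
            Kmax = float(np.max(self.K))
            if Kmax > 0 and not self.A < Kmax:
                raise ValueError(
                    f"Allee threshold A={self.A} must lie below the carrying "
                    f"capacity K={Kmax}"
                )


# Lookup-table resolution for the integrated Allee map.  The grid is
# dense near the threshold A (slow dynamics, high curvature) and spans
# [0, 4K] so that propagule-inflated cells above K still interpolate.
_TABLE_LOW = 257
_TABLE_HIGH = 512


@lru_cache(maxsize=64)
def _allee_flow_table(r: float, K: float, A: float) -> tuple[np.ndarray, np.ndarray]:
    """One-step flow N -> phi_1(N) of dN/dt = rN(1-N/K)(N/A-1), tabulated."""
    lo = np.linspace(0.0, min(3.0 * A, K), _TABLE_LOW)
    hi = np.geomspace(max(lo[-1], 1e-9), 4.0 * K, _TABLE_HIGH)
    grid = np.unique(np.concatenate([lo, hi, [A, K]]))

    def rhs(_t, y):
        return r * y * (1.0 - y / K) * (y / A - 1.0)

    sol = solve_ivp(rhs, (0.0, 1.0), grid, method="LSODA",
                    rtol=1e-9, atol=1e-12, t_eval=[1.0])
    out = np.maximum(sol.y[:, -1], 0.0)
    # pin the exact fixed points against residual solver drift
    for fp in (0.0, A, K):
        out[grid == fp] = fp
    return grid, out


def _allee_step(N: np.ndarray, r: float, K: np.ndarray, A: float) -> np.ndarray:
    out = np.zeros_like(N)
    for k in np.unique(K[K > 0]):
        grid, table = _allee_flow_table(float(r), float(k), float(A))
        sel = K == k
        out[sel] = np.interp(np.minimum(N[sel], grid[-1]), grid, table)
    return out


def grow(state: np.ndarray, spec: GrowthSpec, K_map=None, rng=None) -> np.ndarray:
    """Apply one step of the growth map to an abundance grid.

    ``K_map`` overrides ``spec.K``; cells where K <= 0 (unsuitable or
    nodata) are set to zero.  Negative intermediate values (overshoot at
    large r in the difference-equation families) are clamped to zero
    rather than raised.
    """
    N = np.asarray(state, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundances must be non-negative")
    K = np.asarray(spec.K if K_map is None else K_map, dtype=float)
    if K.ndim == 2 and K.shape != N.shape:
        raise ValueError(f"K_map shape {K.shape} != state shape {N.shape}")
    K = np.broadcast_to(K, N.shape)

    habitable = K > 0
    Ksafe = np.where(habitable, K, 1.0)
    if spec.family == "logistic":
        out = N + spec.r * N * (1.0 - N / Ksafe)
    elif spec.family == "beverton_holt":
        er = np.exp(spec.r)
        out = er * N / (1.0 + (er - 1.0) * N / Ksafe)
    elif spec.family == "ricker":
        out = N * np.exp(spec.r * (1.0 - N / Ksafe))
    else:  # allee_logistic
        out = _allee_step(N, spec.r, K, spec.A)
    out = np.where(habitable, out, 0.0)
    out = np.maximum(out, 0.0)
    if spec.stochastic:
        if rng is None:
            raise ValueError("stochastic growth requires an rng")
        out = rng.poisson(out).astype(float)
    return out
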