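"""Post-dispersal survival filtering.

After growth and dispersal, each cell's population is filtered against a
survival-probability layer (or a single scalar for homogeneous
landscapes).  In abundance mode survivors are a binomial thinning of the
cell's individuals; in presence mode an occupied cell persists with the
cell's survival probability.  ``scope='all'`` filters everything every
step; ``scope='new_only'`` filters only individuals (or cells) that were
not present at the start of the step — an establishment filter that
leaves long-established populations untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurvivalSpec", "apply_survival"]


@dataclass
class SurvivalSpec:
    """Survival layer (scalar or per-cell array in [0, 1]) and scope."""

    s: float | np.ndarray = 1.0
    scope: str = "all"

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if np.any(~np.isfinite(s)) or s.min() < 0.0 or s.max() > 1.0:
            raise ValueError("survival probabilities must be finite and in [0, 1]")
        if self.scope not in ("all", "new_only"):
            raise ValueError("scope must be 'all' or 'new_only'")


def _thin(N: np.ndarray, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Binomial thinning of an abundance grid, elementwise.

    Deterministic where s is exactly 0 or 1 (preserving real-valued
    densities); elsewhere the abundance is rounded to the nearest
    integer for the binomial draw.
    """
    out = N * s  # exact for s in {0, 1}; overwritten elsewhere
    mid = (s > 0.0) & (s < 1.0)
    if np.any(mid):
        n_int = np.rint(N[mid]).astype(np.int64)
        out[mid] = rng.binomial(n_int, np.broadcast_to(s, N.shape)[mid]).astype(float)
    return out


def apply_survival(
    state: np.ndarray,
    spec: SurvivalSpec,
    previous_state: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "abundance",
) -> np.ndarray:
    """Filter a population state through the survival layer.

    ``previous_state`` (the state at the start of the step) is required
    when ``scope='new_only'``: only the increment over it is filtered.
    """
    s = np.asarray(spec.s, dtype=float)
    if s.ndim == 2 and s.shape != state.shape:
        raise ValueError(f"survival map shape {s.shape} != state shape {state.shape}")
    s_full = np.broadcast_to(s, state.shape)
    if rng is None:
        raise ValueError("apply_survival requires an rng")

    if mode == "presence":
        occ = state.astype(bool)
        keep = rng.random(state.shape) < s_full
        if spec.scope == "new_only":
            if previous_state is None:
                raise ValueError("scope='new_only' requires previous_state")
            prev = previous_state.astype(bool)
            return occ & (keep | prev)
        return occ & keep

    N = np.asarray(state, dtype=float)
    if spec.scope == "new_only":
        if previous_state is None:
            raise ValueError("scope='new_only' requires previous_state")
        prev = np.asarray(previous_state, dtype=float)
        resident = np.minimum(N, prev)
        newcomers = N - resident
        return resident + _thin(newcomers, s_full, rng)
    return _thin(N, s_full, rng)
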