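"""Seeding, growth schedule, and shape-dependent division.

The monolayer grows by a fixed-cadence schedule: circular cells of
radius ``r0`` are seeded at random non-overlapping positions, relax for
``relax_time`` hours without dividing, and then exactly one cell
divides every ``division_period`` MCS until the terminal count is
reached. Which cell divides is stochastic, with probability

    p_i = Z^{-1} exp(A_i / A_pref - alpha * AR_i / AR_pref),

so larger and (for ``alpha > 0``) more isotropic cells divide more
often — the mechanism that couples packing geometry to local growth.
A ``uniform_random`` mode bypasses the weights as a control.

Division is along the long axis: both daughters get the parent's
orientation and ``0.4x`` axes, centered at ``+-0.4 a`` along the major
axis so they touch at the parent's center and stay inside its
footprint. Cell area is intentionally not conserved at division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels as K
from . import _rng
from .model_core import Cell, ModelParams, RidgePattern, SimState

__all__ = [
    "GrowthSchedule",
    "initialize_state",
    "division_weights",
    "perform_division",
    "growth_step",
]

#: Neighbor-list row capacity safety factor over the terminal-density
#: expectation inside the padded cutoff ellipse.
_NBR_SAFETY = 2.5


@dataclass
class GrowthSchedule:
    """Growth-phase bookkeeping derived from the model parameters."""

    relax_time: float        # h
    division_period: int     # MCS
    terminal_count: int
    alpha: float
    mode: str

    @classmethod
    def from_params(cls, params: ModelParams) -> "GrowthSchedule":
        return cls(
            relax_time=params.relax_time,
            division_period=params.division_period,
            terminal_count=params.terminal_count_effective,
            alpha=params.alpha,
            mode=params.division_mode,
        )


def _max_neighbors(params: ModelParams) -> int:
    pad_area = math.pi * (params.rc_maj + params.skin) * (params.rc_min + params.skin)
    dens = params.terminal_count_effective / params.L ** 2
    est = int(math.ceil(pad_area * dens * _NBR_SAFETY)) + 16
    return min(max(est, 32), max(params.terminal_count_effective - 1, 1))


def initialize_state(params: ModelParams, seed: int = 1,
                     rng: Optional[np.ndarray] = None,
                     max_attempts_per_cell: int = 20000) -> SimState:
    """Seed the initial monolayer: circular cells at random positions.

    Cells of radius ``r0`` are placed by rejection sampling (any pair
    of centers closer than ``2 r0`` under the minimum image is
    rejected), then given uniformly random orientations and unit
    polarity directions. Identical seed and parameters give identical
    configurations.
    """
    params = params.validate()
    if rng is None:
        rng = _rng.seed_state(seed)
    pattern = RidgePattern.from_params(params)
    n_init = params.n_init_effective
    terminal = max(params.terminal_count_effective, n_init)
    state = SimState.allocate(params, pattern, rng, capacity=terminal + 2)

    L = params.L
    min_d2 = (2.0 * params.r0) ** 2
    for i in range(n_init):
        placed = False
        for _ in range(max_attempts_per_cell):
            cx = L * _rng.uniform(rng)
            cy = L * _rng.uniform(rng)
            ok = True
            for j in range(i):
                dx = K.k_wrap(state.x[j] - cx, L)
                dy = K.k_wrap(state.y[j] - cy, L)
                if dx * dx + dy * dy < min_d2:
                    ok = False
                    break
            if ok:
                state.x[i], state.y[i] = cx, cy
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i} without overlap after "
                f"{max_attempts_per_cell} attempts; box too crowded")
    for i in range(n_init):
        state.phi[i] = 2.0 * math.pi * _rng.uniform(rng)
    for i in range(n_init):
        th = 2.0 * math.pi * _rng.uniform(rng)
        state.px[i], state.py[i] = math.cos(th), math.sin(th)
    state.a[:n_init] = params.r0
    state.b[:n_init] = params.r0
    state.ids[:n_init] = np.arange(n_init)
    state.parent[:n_init] = -1
    state.n = n_init
    state.next_id = n_init
    state.mcs = 0

    maxn = _max_neighbors(params)
    state.nbr = np.zeros((state.capacity, maxn), dtype=np.int32)
    state.nnbr = np.zeros(state.capacity, dtype=np.int32)

    from .dynamics import refresh_caches

    refresh_caches(state)
    return state


def division_weights(cells: Sequence, alpha: float,
                     params: ModelParams) -> np.ndarray:
    """Normalized division probabilities for a cell collection.

    Computed with a max-shifted exponent so the normalization stays
    exact for thousands of cells with extreme areas.
    """
    if len(cells) == 0:
        raise ValueError("division_weights needs at least one cell")
    try:
        A = np.array([c.area for c in cells])
        AR = np.array([c.aspect_ratio for c in cells])
    except AttributeError:  # DataFrame-like input
        A = np.pi * np.asarray(cells["a"]) * np.asarray(cells["b"])
        AR = np.asarray(cells["a"]) / np.asarray(cells["b"])
    expo = A / params.A_pref - alpha * AR / params.AR_pref
    w = np.exp(expo - expo.max())
    return w / w.sum()


def perform_division(state: SimState, rng: Optional[np.ndarray] = None) -> SimState:
    """Execute one division event and rebuild the neighbor lists."""
    from .dynamics import ensure_engine

    ensure_engine(state)
    if rng is None:
        rng = state.rng
    p = state.params
    meta = np.array([state.n, state.mcs, state.next_id], dtype=np.int64)
    isel = K.k_divide(rng, meta, state.x, state.y, state.a, state.b,
                      state.phi, state.cphi, state.sphi,
                      state.px, state.py, state.ids, state.parent,
                      state._wbuf, state._pvec)
    state.n = int(meta[K.META_N])
    state.next_id = int(meta[K.META_NEXT_ID])
    st = K.k_build_lists(state.x, state.y, state.cphi, state.sphi, state.n,
                         state.nbr, state.nnbr, state.moved, state.rotm,
                         p.L, p.rc_maj, p.rc_min, p.skin)
    if st != K.STATUS_OK:
        raise RuntimeError("neighbor-list capacity exceeded at division")
    for i in (isel, state.n - 1):
        ups = K.k_upsilon(state.x[i], state.y[i], state.a[i], state.b[i],
                          state.cphi[i], state.sphi[i], state._fsx, state._fsy,
                          state._pvec[K.PV.PCX], state._pvec[K.PV.PCY],
                          p.L, state._pvec[K.PV.SPACING],
                          state._pvec[K.PV.HALF_WIDTH], state._pvec[K.PV.KMAX])
        state.ridge_cache[i] = state.pattern.k_r * ups
    return state


def growth_step(state: SimState) -> SimState:
    """Division scheduler hook, called at each MCS boundary.

    No-op unless the MCS clock sits on a division-period boundary past
    the relaxation phase and the terminal count has not been reached;
    otherwise performs exactly one division.
    """
    p = state.params
    if state.mcs % p.division_period != 0:
        return state
    if state.mcs < p.relax_mcs:
        return state
    if state.n >= p.terminal_count_effective:
        return state
    return perform_division(state)
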