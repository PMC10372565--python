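"""Metropolis Monte Carlo engine: proposals, acceptance, motility,
polarity feedback and reversals, MCS bookkeeping.

Two execution paths share one random stream and one draw order:

* the *fast path* (:func:`run`, :func:`run_mcs`) drives the fused numba
  kernel of :mod:`spindlemc._kernels` and is what simulations use;
* the *reference path* (:func:`run_mcs_reference`,
  :func:`metropolis_step`) is a pure-Python orchestration over the
  numpy energy functions of :mod:`spindlemc.model_core` and
  :mod:`spindlemc.interactions`. It exists so the compiled engine can
  be checked draw-for-draw against an independently written
  implementation on small systems.

Draw order per MCS (the reproducibility contract, see docs/methods.md):
Fisher–Yates permutation of cells (descending index), then per cell one
kind draw plus the kind's parameter draws, plus exactly one acceptance
draw for every energy-evaluated proposal (resize proposals violating
``a >= b > 0`` are rejected outright without an acceptance draw); then
per-cell polarity feedback (no draws); at flip-period boundaries one
reversal draw per cell; then, in the growth phase, the division
draw(s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np

from . import _kernels as K
from . import _rng
from .model_core import (
    Cell,
    ModelParams,
    SimState,
    core_energy,
    minimum_image,
    ridge_energy,
    shape_energy,
)
from .interactions import in_interaction_cutoff, pair_energy

__all__ = [
    "Proposal",
    "propose",
    "motility_delta",
    "local_energy",
    "metropolis_step",
    "update_polarity",
    "flip_polarities",
    "run_mcs",
    "run_mcs_reference",
    "run",
]

MOVE_KINDS = ("displace", "rotate", "resize_a", "resize_b")


@dataclass
class Proposal:
    """A single proposed Monte Carlo move."""

    kind: str
    delta: Union[np.ndarray, float]


# --------------------------------------------------------------------------
# engine plumbing
# --------------------------------------------------------------------------

def ensure_engine(state: SimState) -> None:
    """Attach kernel parameter vector and scratch arrays to the state."""
    if getattr(state, "_pvec", None) is not None:
        return
    cap = state.capacity
    state._pvec = K.params_vector(state.params, state.pattern)
    state._fsx, state._fsy = K.feeler_offsets(state.params)
    state._perm = np.zeros(cap, dtype=np.int64)
    state._dxr = np.zeros(cap, dtype=np.float64)
    state._dyr = np.zeros(cap, dtype=np.float64)
    state._wbuf = np.zeros(cap, dtype=np.float64)
    state.counters = np.zeros(8, dtype=np.int64)


def refresh_caches(state: SimState) -> None:
    """Rebuild neighbor lists and ridge-energy caches from scratch.

    Call after mutating cell arrays outside the engine. Resets the
    accumulated-motion metric, so it perturbs rebuild timing; the engine
    itself never calls this mid-run.
    """
    ensure_engine(state)
    p = state.params
    n = state.n
    np.cos(state.phi[:n], out=state.cphi[:n])
    np.sin(state.phi[:n], out=state.sphi[:n])
    st = K.k_build_lists(state.x, state.y, state.cphi, state.sphi, n,
                         state.nbr, state.nnbr, state.moved, state.rotm,
                         p.L, p.rc_maj, p.rc_min, p.skin)
    if st != K.STATUS_OK:
        raise RuntimeError("neighbor-list capacity exceeded; increase max_neighbors")
    K.k_ridge_fill(state.x, state.y, state.a, state.b, state.cphi, state.sphi,
                   n, state.ridge_cache, state._fsx, state._fsy, state._pvec)


def _meta(state: SimState) -> np.ndarray:
    meta = np.zeros(3, dtype=np.int64)
    meta[K.META_N] = state.n
    meta[K.META_MCS] = state.mcs
    meta[K.META_NEXT_ID] = state.next_id
    return meta


# --------------------------------------------------------------------------
# fast path
# --------------------------------------------------------------------------

def run_mcs(state: SimState, n_mcs: int = 1, growth: bool = True) -> SimState:
    """Advance the state by ``n_mcs`` full Monte Carlo steps (compiled)."""
    ensure_engine(state)
    meta = _meta(state)
    pv = state._pvec
    pv[K.PV.GROWTH_ON] = 1.0 if growth else 0.0
    status = K.run_block(
        state.rng, meta, state.x, state.y, state.a, state.b, state.phi,
        state.cphi, state.sphi, state.px, state.py, state.ids, state.parent,
        state.nbr, state.nnbr, state.moved, state.rotm, state.ridge_cache,
        state._perm, state._dxr, state._dyr, state._wbuf,
        state._fsx, state._fsy, pv, n_mcs, state.counters)
    if status != K.STATUS_OK:
        raise RuntimeError("neighbor-list capacity exceeded during run")
    state.n = int(meta[K.META_N])
    state.mcs = int(meta[K.META_MCS])
    state.next_id = int(meta[K.META_NEXT_ID])
    return state


def run(state: SimState, n_mcs: int, record_at: Sequence[int] = (),
        log_path: Optional[str] = None, log_every: int = 1000,
        growth: bool = True) -> Dict[int, "object"]:
    """Run the engine, capturing snapshots at the requested MCS values.

    Returns ``{mcs: DataFrame}`` for every requested record point that
    falls inside the run (the block structure never perturbs the
    trajectory — recording is purely observational). Acceptance-rate
    logs are appended to ``log_path`` as JSON lines every ``log_every``
    MCS.
    """
    ensure_engine(state)
    end = state.mcs + n_mcs
    points = sorted({int(m) for m in record_at if state.mcs <= m <= end})
    frames: Dict[int, object] = {}
    log_f = open(log_path, "a") if log_path else None
    try:
        if state.mcs in points:
            frames[state.mcs] = state.to_frame()
            points.remove(state.mcs)
        while state.mcs < end:
            nxt = end
            if points:
                nxt = min(nxt, points[0])
            if log_f is not None:
                nxt = min(nxt, (state.mcs // log_every + 1) * log_every)
            before = state.counters.copy()
            run_mcs(state, nxt - state.mcs, growth=growth)
            if log_f is not None and state.mcs % log_every == 0:
                _write_log_line(log_f, state, before)
            if points and state.mcs == points[0]:
                frames[state.mcs] = state.to_frame()
                points.pop(0)
    finally:
        if log_f is not None:
            log_f.close()
    return frames


def _write_log_line(fh, state: SimState, counters_before: np.ndarray) -> None:
    d = state.counters - counters_before
    rates = {}
    for k, name in enumerate(MOVE_KINDS):
        rates[name] = float(d[4 + k] / d[k]) if d[k] > 0 else None
    n = state.n
    mean_pol = float(np.mean(np.hypot(state.px[:n], state.py[:n]))) if n else 0.0
    fh.write(json.dumps({
        "mcs": state.mcs, "n_cells": n, "acceptance": rates,
        "mean_polarity": mean_pol,
    }) + "\n")
    fh.flush()


# --------------------------------------------------------------------------
# reference path (pure Python orchestration, numpy energies)
# --------------------------------------------------------------------------

def propose(cell: Cell, rng: np.ndarray, params: ModelParams) -> Proposal:
    """Draw one move proposal from the move mix.

    Consumes the stream exactly as the compiled engine does: one kind
    draw, then two uniforms for a displacement (magnitude fraction and
    direction angle) or one uniform for the other kinds.
    """
    m = params.move_mix
    kind = K.k_draw_kind(rng, m[0], m[0] + m[1], m[0] + m[1] + m[2])
    if kind == 0:
        mag = params.delta_r * _rng.uniform(rng)
        psi = 2.0 * math.pi * _rng.uniform(rng)
        return Proposal("displace", np.array([mag * math.cos(psi),
                                              mag * math.sin(psi)]))
    if kind == 1:
        return Proposal("rotate", 2.0 * params.delta_phi * (_rng.uniform(rng) - 0.5))
    if kind == 2:
        return Proposal("resize_a", params.delta_a * (_rng.uniform(rng) - 0.5))
    return Proposal("resize_b", params.delta_b * (_rng.uniform(rng) - 0.5))


def motility_delta(cell: Cell, dr: np.ndarray, params: ModelParams) -> float:
    """Motility energy change for a displacement proposal.

    ``dE = -k_move * (Pi . dr) / |Pi|`` with ``Pi = (u.p) u``; the
    magnitude of the polarity is irrelevant, only its sign along the
    major axis. Zero when the polarity is perpendicular to the axis
    (``Pi = 0`` convention).
    """
    u = cell.u
    udotp = float(u @ cell.polarity)
    if udotp == 0.0:
        return 0.0
    return -params.k_move * math.copysign(1.0, udotp) * float(u @ np.asarray(dr))


def local_energy(cell_id: int, state: SimState) -> float:
    """Shape + core + ridge + pair energy of one cell (reference path).

    The pair sum runs over the cell's neighbor list with the exact
    elliptical cutoff re-applied (the list is a padded superset). The
    motility term is not part of the local energy; it only enters as a
    delta for displacement proposals.
    """
    p = state.params
    ci = state.cell(cell_id)
    e = shape_energy(ci, p) + core_energy(ci, p) + ridge_energy(ci, state.pattern, p)
    for j in state.nbr[cell_id, : state.nnbr[cell_id]]:
        cj = state.cell(int(j))
        if in_interaction_cutoff(ci, cj, p.L, p):
            e += pair_energy(ci, cj, p.L, p)
    return e


def metropolis_step(cell_id: int, proposal: Proposal, state: SimState,
                    rng: Optional[np.ndarray] = None) -> bool:
    """Apply one proposal with the Metropolis criterion (reference path).

    Mutates the state on acceptance and returns whether the move was
    accepted. Resize proposals that would violate ``a >= b > 0`` are
    rejected outright without consuming an acceptance draw. On an
    accepted rotation the polarity co-rotates by the same angle.
    """
    ensure_engine(state)
    if rng is None:
        rng = state.rng
    p = state.params
    i = cell_id
    e_before = local_energy(i, state)
    old = (state.x[i], state.y[i], state.a[i], state.b[i], state.phi[i])
    extra = 0.0
    if proposal.kind == "displace":
        extra = motility_delta(state.cell(i), proposal.delta, p)
        dx, dy = proposal.delta
        state.x[i] = state.x[i] + dx - p.L * math.floor((state.x[i] + dx) / p.L)
        state.y[i] = state.y[i] + dy - p.L * math.floor((state.y[i] + dy) / p.L)
    elif proposal.kind == "rotate":
        phin = old[4] + proposal.delta
        state.phi[i] = phin - 2.0 * math.pi * math.floor(phin / (2.0 * math.pi))
    elif proposal.kind == "resize_a":
        an = old[2] + proposal.delta
        if an < old[3]:
            return False
        state.a[i] = an
    elif proposal.kind == "resize_b":
        bn = old[3] + proposal.delta
        if bn <= 0.0 or old[2] < bn:
            return False
        state.b[i] = bn
    else:
        raise ValueError(f"unknown proposal kind {proposal.kind!r}")
    e_after = local_energy(i, state)
    dE = e_after - e_before + extra
    # the acceptance draw is consumed unconditionally (see k_metro_accept)
    u = _rng.uniform(rng)
    accepted = dE <= 0.0 or u < math.exp(-dE / p.T)
    if not accepted:
        state.x[i], state.y[i], state.a[i], state.b[i], state.phi[i] = old
        return False
    if proposal.kind == "rotate":
        state.cphi[i] = math.cos(state.phi[i])
        state.sphi[i] = math.sin(state.phi[i])
        cd, sd = math.cos(proposal.delta), math.sin(proposal.delta)
        pxn = cd * state.px[i] - sd * state.py[i]
        pyn = sd * state.px[i] + cd * state.py[i]
        state.px[i], state.py[i] = pxn, pyn
        state.rotm[i] += p.rc_maj * abs(proposal.delta)
        if state.rotm[i] > K.TRIG_FRAC * p.skin:
            st = K.k_build_row(i, state.x, state.y, state.cphi, state.sphi,
                               state.n, state.nbr, state.nnbr, state.rotm,
                               p.L, p.rc_maj, p.rc_min, p.skin)
            if st != K.STATUS_OK:
                raise RuntimeError("neighbor-list capacity exceeded")
    elif proposal.kind == "displace":
        state.moved[i] += float(np.hypot(*proposal.delta))
        if state.moved[i] > K.TRIG_FRAC * p.skin:
            st = K.k_build_lists(state.x, state.y, state.cphi, state.sphi,
                                 state.n, state.nbr, state.nnbr, state.moved,
                                 state.rotm, p.L, p.rc_maj, p.rc_min, p.skin)
            if st != K.STATUS_OK:
                raise RuntimeError("neighbor-list capacity exceeded")
    return True


def update_polarity(cell: Cell, dr_realized: np.ndarray,
                    params: ModelParams) -> np.ndarray:
    """Polarity feedback ``p <- (1 - 1/tau_pol) p + dr``.

    ``dr_realized`` is the displacement actually performed this MCS
    (zero if none was proposed or the proposal was rejected).
    """
    return (1.0 - 1.0 / params.tau_pol) * cell.polarity + np.asarray(dr_realized, float)


def flip_polarities(state: SimState, rng: Optional[np.ndarray] = None) -> SimState:
    """Stochastic polarity reversal: each cell flips with the per-check
    probability, independently (one draw per cell, index order)."""
    if rng is None:
        rng = state.rng
    p = state.params.tau_flip_prob
    for i in range(state.n):
        if _rng.uniform(rng) < p:
            state.px[i] = -state.px[i]
            state.py[i] = -state.py[i]
    return state


def run_mcs_reference(state: SimState, growth: bool = True) -> SimState:
    """One full MCS through the pure-Python path (same draws as kernel)."""
    from .division import growth_step

    ensure_engine(state)
    p = state.params
    n = state.n
    perm = np.arange(n, dtype=np.int64)
    _rng.shuffle(state.rng, perm, n)
    dxr = np.zeros(n)
    dyr = np.zeros(n)
    proposed_mode = p.polarity_feedback == "proposed"
    for k in range(n):
        i = int(perm[k])
        prop = propose(state.cell(i), state.rng, p)
        if prop.kind == "displace" and proposed_mode:
            dxr[i], dyr[i] = prop.delta
        accepted = metropolis_step(i, prop, state)
        if accepted and prop.kind == "displace" and not proposed_mode:
            dxr[i], dyr[i] = prop.delta
    keep = 1.0 - 1.0 / p.tau_pol
    state.px[:n] = keep * state.px[:n] + dxr
    state.py[:n] = keep * state.py[:n] + dyr
    state.mcs += 1
    if state.mcs % p.flip_period == 0:
        flip_polarities(state)
    if growth:
        growth_step(state)
    return state
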