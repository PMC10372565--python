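"""Compiled Monte Carlo engine (numba).

This module re-implements the energies of :mod:`spindlemc.model_core`
and :mod:`spindlemc.interactions` as scalar njit functions and fuses
them into a single per-block sweep kernel, so that full growth runs
(tens of millions of single-cell moves) execute at native speed on one
core. The numpy modules remain the reference implementations; the test
suite cross-checks the scalar kernels against them to 1e-9 relative
tolerance and checks a full short trajectory of the fused kernel
against the pure-Python engine draw for draw.

Performance notes: per-cell orientation cosines are cached in the
``cphi``/``sphi`` state arrays (kept exactly equal to
``cos(phi)``/``sin(phi)`` by every accepting code path), and the
elliptical cutoff test uses precomputed reciprocal squared semi-axes.

Model parameters travel as a flat float64 vector (indices below) so the
kernel signature stays stable. All randomness flows through the
explicit xoshiro256** state of :mod:`spindlemc._rng`; the draw order
per Monte Carlo step is fixed and documented in ``docs/methods.md``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._rng import uniform, rand_below

__all__ = ["PV", "params_vector", "feeler_offsets"]


# --- indices into the parameter vector ------------------------------------
class PV:
    T = 0
    DELTA_R = 1
    DELTA_PHI = 2
    DELTA_A = 3
    DELTA_B = 4
    A_PREF = 5
    AR_PREF = 6
    K_A = 7
    K_AR = 8
    K_CORE = 9
    EPS0 = 10
    MU = 11
    NU = 12
    RC_MAJ = 13
    RC_MIN = 14
    SKIN = 15
    K_MOVE = 16
    TAU_POL = 17
    FLIP_PROB = 18
    FLIP_PERIOD = 19
    K_R = 20
    SPACING = 21
    HALF_WIDTH = 22
    L = 23
    PCX = 24
    PCY = 25
    KMAX = 26          # number of ridge rings
    MIX0 = 27          # cumulative move-mix thresholds
    MIX1 = 28
    MIX2 = 29
    RELAX_MCS = 30
    DIV_PERIOD = 31
    TERMINAL = 32
    DAUGHTER_F = 33
    ALPHA = 34
    DIV_MODE = 35      # 0 shape_dependent, 1 uniform_random
    POL_FEEDBACK = 36  # 0 accepted displacement, 1 proposed
    DAUGHTER_POL = 37  # 0 inherit, 1 random
    GROWTH_ON = 38
    SIZE = 39


# numba resolves plain module-level constants at compile time, class
# attributes it does not; mirror the PV indices as PV_<NAME> globals.
for _name, _val in list(PV.__dict__.items()):
    if not _name.startswith("_"):
        globals()["PV_" + _name] = _val


SCALED_DISTANCE_FLOOR = 1e-3

# meta indices
META_N = 0
META_MCS = 1
META_NEXT_ID = 2

STATUS_OK = 0
STATUS_NBR_OVERFLOW = 1


def params_vector(params, pattern) -> np.ndarray:
    """Flatten ModelParams + RidgePattern into the kernel vector."""
    pv = np.zeros(PV.SIZE, dtype=np.float64)
    pv[PV_T] = params.T
    pv[PV_DELTA_R] = params.delta_r
    pv[PV_DELTA_PHI] = params.delta_phi
    pv[PV_DELTA_A] = params.delta_a
    pv[PV_DELTA_B] = params.delta_b
    pv[PV_A_PREF] = params.A_pref
    pv[PV_AR_PREF] = params.AR_pref
    pv[PV_K_A] = params.k_A
    pv[PV_K_AR] = params.k_AR
    pv[PV_K_CORE] = params.k_core
    pv[PV_EPS0] = params.eps0
    pv[PV_MU] = params.mu
    pv[PV_NU] = params.nu
    pv[PV_RC_MAJ] = params.rc_maj
    pv[PV_RC_MIN] = params.rc_min
    pv[PV_SKIN] = params.skin
    pv[PV_K_MOVE] = params.k_move
    pv[PV_TAU_POL] = params.tau_pol
    pv[PV_FLIP_PROB] = params.tau_flip_prob
    pv[PV_FLIP_PERIOD] = params.flip_period
    pv[PV_K_R] = pattern.k_r
    pv[PV_SPACING] = pattern.ring_spacing
    pv[PV_HALF_WIDTH] = pattern.ring_width / 2.0
    pv[PV_L] = params.L
    pv[PV_PCX] = pattern.center[0]
    pv[PV_PCY] = pattern.center[1]
    pv[PV_KMAX] = float(len(pattern.radii))
    m = params.move_mix
    pv[PV_MIX0] = m[0]
    pv[PV_MIX1] = m[0] + m[1]
    pv[PV_MIX2] = m[0] + m[1] + m[2]
    pv[PV_RELAX_MCS] = params.relax_mcs
    pv[PV_DIV_PERIOD] = params.division_period
    pv[PV_TERMINAL] = params.terminal_count_effective
    pv[PV_DAUGHTER_F] = params.daughter_factor
    pv[PV_ALPHA] = params.alpha
    pv[PV_DIV_MODE] = 0.0 if params.division_mode == "shape_dependent" else 1.0
    pv[PV_POL_FEEDBACK] = 0.0 if params.polarity_feedback == "accepted" else 1.0
    pv[PV_DAUGHTER_POL] = 0.0 if params.daughter_polarity == "inherit" else 1.0
    pv[PV_GROWTH_ON] = 1.0
    return pv


def feeler_offsets(params) -> tuple:
    """Unit-ellipse feeler coordinates (sx, sy) for the overlap estimate."""
    scales = np.arange(params.n_feeler_rings, 0, -1) / params.n_feeler_rings
    theta = 2.0 * np.pi * np.arange(params.n_feeler_points) / params.n_feeler_points
    sx = np.outer(scales, np.cos(theta)).ravel()
    sy = np.outer(scales, np.sin(theta)).ravel()
    return np.ascontiguousarray(sx), np.ascontiguousarray(sy)


# --------------------------------------------------------------------------
# scalar pieces
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def k_wrap(d, L):
    """Minimum-image wrap of one component into [-L/2, L/2).

    Branch-select form, exact for |d| < L (always true for differences
    of in-box coordinates).
    """
    if d >= 0.5 * L:
        return d - L
    elif d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def k_wrap_pos(v, L):
    """Wrap a coordinate into the box [0, L)."""
    return v - L * math.floor(v / L)


@njit(cache=True)
def k_shape_core(aa, bb, A_pref, AR_pref, kA, kAR, kcore):
    """Geometric energies: quartic shape penalties + core barrier."""
    dA = (math.pi * aa * bb - A_pref) / A_pref
    dR = (aa / bb - AR_pref) / AR_pref
    e = kA * (dA * dA - dA * dA * dA / 3.0 + 4.0 * dA * dA * dA * dA)
    e += kAR * (dR * dR - dR * dR * dR / 3.0 + 4.0 * dR * dR * dR * dR)
    a2 = aa * aa
    b2 = bb * bb
    return e + kcore * (1.0 / (a2 * a2) + 1.0 / (b2 * b2))


@njit(cache=True, fastmath=True)
def k_upsilon(cx, cy, aa, bb, cphi, sphi, fsx, fsy,
              pcx, pcy, L, spacing, half_w, kmax):
    """Fraction of feeler points lying on ridge annuli.

    Every feeler point lies within distance ``a`` of the cell center,
    so when the center's distance to the nearest ring differs by more
    than ``a + half_w`` the overlap is exactly zero and the point loop
    is skipped.
    """
    hL = 0.5 * L
    ox = k_wrap(cx - pcx, L)
    oy = k_wrap(cy - pcy, L)
    inv_sp = 1.0 / spacing
    rc = math.sqrt(ox * ox + oy * oy)
    kc = math.floor(rc * inv_sp + 0.5)
    if kc < 1.0:
        kc = 1.0
    elif kc > kmax:
        kc = kmax
    if abs(rc - kc * spacing) > aa + half_w:
        return 0.0
    ac = aa * cphi
    as_ = aa * sphi
    bc = bb * cphi
    bs = bb * sphi
    cnt = 0.0
    for k in range(fsx.shape[0]):
        px = ox + fsx[k] * ac - fsy[k] * bs
        py = oy + fsx[k] * as_ + fsy[k] * bc
        if px >= hL:
            px -= L
        elif px < -hL:
            px += L
        if py >= hL:
            py -= L
        elif py < -hL:
            py += L
        r = math.sqrt(px * px + py * py)
        kk = math.floor(r * inv_sp + 0.5)
        on = (kk >= 1.0) and (kk <= kmax) and (abs(r - kk * spacing) <= half_w)
        cnt += 1.0 if on else 0.0
    return cnt / fsx.shape[0]


@njit(cache=True, inline="always")
def k_in_cutoff(dx, dy, c, s, inv_am2, inv_bm2):
    """Is the offset (dx, dy) inside the cutoff ellipse of a cell with
    orientation (c, s)? Semi-axes enter as reciprocal squares."""
    along = dx * c + dy * s
    perp = -dx * s + dy * c
    return along * along * inv_am2 + perp * perp * inv_bm2 <= 1.0


@njit(cache=True, inline="always")
def _gb_core(dx, dy, r2, gxx, gyy, gxy, e1, f1, d1s, e2, f2, d2s,
             dot, eps0, mu, nu):
    """Gay–Berne 12-6 energy from precomputed shape factors.

    Uses the scaled separation in the algebraic form
    ``r = sqrt(r2)/sigma0 - sigma/sigma0 + 1`` with
    ``sigma/sigma0 = 1/sqrt(sigma0^2 q)``, which needs one fewer root
    than the textbook grouping. The quadratic form ``q`` is clamped
    below to keep transient coincident centers finite (they produce a
    huge repulsion that Metropolis then rejects).
    """
    det = gxx * gyy - gxy * gxy
    q = (dx * dx * gyy - 2.0 * dx * dy * gxy + dy * dy * gxx) / (det * r2)
    if q < 1e-12:
        q = 1e-12
    s0sq = d1s + d2s
    chi2 = (e1 * e2) / (f1 * f2)
    eps_a2 = 1.0 / (1.0 - chi2 * dot * dot)
    eps_b = s0sq * q
    if nu != 1.0:
        eps_a = math.sqrt(eps_a2) ** nu
    else:
        eps_a = math.sqrt(eps_a2)
    if mu != 1.0:
        eps_b = eps_b ** mu
    eps = eps0 * eps_a * eps_b
    r = math.sqrt(r2 / s0sq) - 1.0 / math.sqrt(s0sq * q) + 1.0
    if r < SCALED_DISTANCE_FLOOR:
        r = SCALED_DISTANCE_FLOOR
    t = 1.0 / r
    t2 = t * t
    t6 = t2 * t2 * t2
    return 4.0 * eps * t6 * (t6 - 1.0)


@njit(cache=True, inline="always")
def k_pair_u(dx, dy, a1, b1, c1, s1, a2, b2, c2, s2, eps0, mu, nu):
    """Gay–Berne 12-6 pair energy for minimum-image offset (dx, dy)."""
    r2 = dx * dx + dy * dy
    if r2 < 1e-24:
        r2 = 1e-24
    l1s = 2.0 * a1 * a1
    d1s = 2.0 * b1 * b1
    l2s = 2.0 * a2 * a2
    d2s = 2.0 * b2 * b2
    e1 = l1s - d1s
    e2 = l2s - d2s
    gxx = e1 * c1 * c1 + d1s + e2 * c2 * c2 + d2s
    gyy = e1 * s1 * s1 + d1s + e2 * s2 * s2 + d2s
    gxy = e1 * c1 * s1 + e2 * c2 * s2
    return _gb_core(dx, dy, r2, gxx, gyy, gxy, e1, l1s + d1s, d1s,
                    e2, l2s + d2s, d2s, c1 * c2 + s1 * s2, eps0, mu, nu)


@njit(cache=True, inline="always")
def k_draw_kind(rng, m0, m1, m2):
    """Sample the move kind from the cumulative move-mix thresholds."""
    u = uniform(rng)
    if u < m0:
        return 0
    elif u < m1:
        return 1
    elif u < m2:
        return 2
    return 3


@njit(cache=True, inline="always")
def k_metro_accept(rng, dE, T):
    """Metropolis criterion: accept with probability min(1, exp(-dE/T)).

    One uniform draw is consumed for every decision, also when
    ``dE <= 0`` guarantees acceptance: this keeps the stream position
    independent of floating-point noise in a near-zero ``dE``, so
    independently computed energies cannot desynchronize trajectories.
    """
    u = uniform(rng)
    if dE <= 0.0:
        return True
    return u < math.exp(-dE / T)


# --------------------------------------------------------------------------
# neighbor lists
# --------------------------------------------------------------------------

#: List padding and rebuild triggers as fractions of the skin length.
#: Guarantee: positional drift of each cell in a pair plus the rotating
#: cell's boundary swing total at most (2*TRIG_POS + TRIG_ROT) * skin =
#: 0.9 * skin between builds, so with PAD = 0.6 * skin every pair within
#: cutoff - 0.3 * skin is always listed (stronger than the documented
#: cutoff - skin contract).
PAD_FRAC = 0.6
TRIG_FRAC = 0.3


@njit(cache=True)
def k_build_lists(x, y, cphi, sphi, n, nbr, nnbr, moved, rotm,
                  L, rc_maj, rc_min, skin):
    """O(N^2) rebuild of all per-cell neighbor lists (padded cutoff)."""
    am = rc_maj + PAD_FRAC * skin
    bm = rc_min + PAD_FRAC * skin
    am2 = am * am
    inv_am2 = 1.0 / (am * am)
    inv_bm2 = 1.0 / (bm * bm)
    maxn = nbr.shape[1]
    for i in range(n):
        nnbr[i] = 0
    for i in range(n):
        ci = cphi[i]
        si = sphi[i]
        for j in range(i + 1, n):
            dx = k_wrap(x[j] - x[i], L)
            dy = k_wrap(y[j] - y[i], L)
            if dx * dx + dy * dy > am2:
                continue
            if k_in_cutoff(dx, dy, ci, si, inv_am2, inv_bm2):
                if nnbr[i] >= maxn:
                    return STATUS_NBR_OVERFLOW
                nbr[i, nnbr[i]] = j
                nnbr[i] += 1
            if k_in_cutoff(-dx, -dy, cphi[j], sphi[j], inv_am2, inv_bm2):
                if nnbr[j] >= maxn:
                    return STATUS_NBR_OVERFLOW
                nbr[j, nnbr[j]] = i
                nnbr[j] += 1
    for i in range(n):
        moved[i] = 0.0
        rotm[i] = 0.0
    return STATUS_OK


@njit(cache=True)
def k_build_row(i, x, y, cphi, sphi, n, nbr, nnbr, rotm,
                L, rc_maj, rc_min, skin):
    """Rebuild only cell i's neighbor list.

    Valid after a rotation of cell i: the one-sided cutoff means i's
    orientation enters no other cell's list, so the O(N) row refresh
    replaces a full O(N^2) rebuild.
    """
    am = rc_maj + PAD_FRAC * skin
    bm = rc_min + PAD_FRAC * skin
    am2 = am * am
    inv_am2 = 1.0 / (am * am)
    inv_bm2 = 1.0 / (bm * bm)
    maxn = nbr.shape[1]
    ci = cphi[i]
    si = sphi[i]
    cnt = 0
    xi = x[i]
    yi = y[i]
    for j in range(n):
        if j == i:
            continue
        dx = k_wrap(x[j] - xi, L)
        dy = k_wrap(y[j] - yi, L)
        if dx * dx + dy * dy > am2:
            continue
        if k_in_cutoff(dx, dy, ci, si, inv_am2, inv_bm2):
            if cnt >= maxn:
                return STATUS_NBR_OVERFLOW
            nbr[i, cnt] = j
            cnt += 1
    nnbr[i] = cnt
    rotm[i] = 0.0
    return STATUS_OK


@njit(cache=True)
def k_ridge_fill(x, y, a, b, cphi, sphi, n, cache, fsx, fsy, pv):
    """Recompute every cell's cached ridge energy."""
    for i in range(n):
        ups = k_upsilon(x[i], y[i], a[i], b[i], cphi[i], sphi[i], fsx, fsy,
                        pv[PV_PCX], pv[PV_PCY], pv[PV_L],
                        pv[PV_SPACING], pv[PV_HALF_WIDTH], pv[PV_KMAX])
        cache[i] = pv[PV_K_R] * ups


# --------------------------------------------------------------------------
# pair-energy deltas
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def k_pair_sum_delta(i, xo, yo, co, so, ao, bo, xn, yn, cn, sn, an, bn,
                     x, y, a, b, cphi, sphi, nbr, nnbr, pv):
    """Pair-energy change of cell i between (old) and (new) fields.

    Both terms apply the exact (unpadded) elliptical cutoff of cell i;
    the neighbor list only supplies candidates. The moved cell's shape
    factors are hoisted out of the candidate loop.
    """
    L = pv[PV_L]
    hL = 0.5 * L
    am = pv[PV_RC_MAJ]
    bm = pv[PV_RC_MIN]
    inv_am2 = 1.0 / (am * am)
    inv_bm2 = 1.0 / (bm * bm)
    eps0 = pv[PV_EPS0]
    mu = pv[PV_MU]
    nu = pv[PV_NU]
    l1so = 2.0 * ao * ao
    d1so = 2.0 * bo * bo
    e1o = l1so - d1so
    f1o = l1so + d1so
    l1sn = 2.0 * an * an
    d1sn = 2.0 * bn * bn
    e1n = l1sn - d1sn
    f1n = l1sn + d1sn
    goxx = e1o * co * co + d1so
    goyy = e1o * so * so + d1so
    goxy = e1o * co * so
    gnxx = e1n * cn * cn + d1sn
    gnyy = e1n * sn * sn + d1sn
    gnxy = e1n * cn * sn
    tot = 0.0
    for idx in range(nnbr[i]):
        j = nbr[i, idx]
        cj = cphi[j]
        sj = sphi[j]
        aj = a[j]
        bj = b[j]
        l2s = 2.0 * aj * aj
        d2s = 2.0 * bj * bj
        e2 = l2s - d2s
        f2 = l2s + d2s
        g2xx = e2 * cj * cj + d2s
        g2yy = e2 * sj * sj + d2s
        g2xy = e2 * cj * sj
        dx = x[j] - xo
        if dx >= hL:
            dx -= L
        elif dx < -hL:
            dx += L
        dy = y[j] - yo
        if dy >= hL:
            dy -= L
        elif dy < -hL:
            dy += L
        al = dx * co + dy * so
        pe = -dx * so + dy * co
        if al * al * inv_am2 + pe * pe * inv_bm2 <= 1.0:
            r2 = dx * dx + dy * dy
            if r2 < 1e-24:
                r2 = 1e-24
            tot -= _gb_core(dx, dy, r2, goxx + g2xx, goyy + g2yy, goxy + g2xy,
                            e1o, f1o, d1so, e2, f2, d2s,
                            co * cj + so * sj, eps0, mu, nu)
        dx = x[j] - xn
        if dx >= hL:
            dx -= L
        elif dx < -hL:
            dx += L
        dy = y[j] - yn
        if dy >= hL:
            dy -= L
        elif dy < -hL:
            dy += L
        al = dx * cn + dy * sn
        pe = -dx * sn + dy * cn
        if al * al * inv_am2 + pe * pe * inv_bm2 <= 1.0:
            r2 = dx * dx + dy * dy
            if r2 < 1e-24:
                r2 = 1e-24
            tot += _gb_core(dx, dy, r2, gnxx + g2xx, gnyy + g2yy, gnxy + g2xy,
                            e1n, f1n, d1sn, e2, f2, d2s,
                            cn * cj + sn * sj, eps0, mu, nu)
    return tot


# Specialized per-move-kind pair deltas. Algebraically identical to
# k_pair_sum_delta; they only hoist the quantities a given move kind
# cannot change (displacements keep shape and orientation, rotations
# keep position and shape, resizes keep position and orientation).

@njit(cache=True, fastmath=True, inline="always")
def k_pair_delta_displace(i, xo, yo, xn, yn, c, s, aa, bb,
                          x, y, a, b, cphi, sphi, nbr, nnbr, pv):
    L = pv[PV_L]
    hL = 0.5 * L
    inv_am2 = 1.0 / (pv[PV_RC_MAJ] * pv[PV_RC_MAJ])
    inv_bm2 = 1.0 / (pv[PV_RC_MIN] * pv[PV_RC_MIN])
    eps0 = pv[PV_EPS0]
    mu = pv[PV_MU]
    nu = pv[PV_NU]
    l1s = 2.0 * aa * aa
    d1s = 2.0 * bb * bb
    e1 = l1s - d1s
    f1 = l1s + d1s
    g1xx = e1 * c * c + d1s
    g1yy = e1 * s * s + d1s
    g1xy = e1 * c * s
    tot = 0.0
    for idx in range(nnbr[i]):
        j = nbr[i, idx]
        cj = cphi[j]
        sj = sphi[j]
        aj = a[j]
        bj = b[j]
        l2s = 2.0 * aj * aj
        d2s = 2.0 * bj * bj
        e2 = l2s - d2s
        f2 = l2s + d2s
        gxx = g1xx + e2 * cj * cj + d2s
        gyy = g1yy + e2 * sj * sj + d2s
        gxy = g1xy + e2 * cj * sj
        dot = c * cj + s * sj
        dx = x[j] - xo
        if dx >= hL:
            dx -= L
        elif dx < -hL:
            dx += L
        dy = y[j] - yo
        if dy >= hL:
            dy -= L
        elif dy < -hL:
            dy += L
        al = dx * c + dy * s
        pe = -dx * s + dy * c
        if al * al * inv_am2 + pe * pe * inv_bm2 <= 1.0:
            r2 = dx * dx + dy * dy
            if r2 < 1e-24:
                r2 = 1e-24
            tot -= _gb_core(dx, dy, r2, gxx, gyy, gxy,
                            e1, f1, d1s, e2, f2, d2s, dot, eps0, mu, nu)
        dx = x[j] - xn
        if dx >= hL:
            dx -= L
        elif dx < -hL:
            dx += L
        dy = y[j] - yn
        if dy >= hL:
            dy -= L
        elif dy < -hL:
            dy += L
        al = dx * c + dy * s
        pe = -dx * s + dy * c
        if al * al * inv_am2 + pe * pe * inv_bm2 <= 1.0:
            r2 = dx * dx + dy * dy
            if r2 < 1e-24:
                r2 = 1e-24
            tot += _gb_core(dx, dy, r2, gxx, gyy, gxy,
                            e1, f1, d1s, e2, f2, d2s, dot, eps0, mu, nu)
    return tot


@njit(cache=True, fastmath=True, inline="always")
def k_pair_delta_rotate(i, xi, yi, co, so, cn, sn, aa, bb,
                        x, y, a, b, cphi, sphi, nbr, nnbr, pv):
    L = pv[PV_L]
    hL = 0.5 * L
    inv_am2 = 1.0 / (pv[PV_RC_MAJ] * pv[PV_RC_MAJ])
    inv_bm2 = 1.0 / (pv[PV_RC_MIN] * pv[PV_RC_MIN])
    eps0 = pv[PV_EPS0]
    mu = pv[PV_MU]
    nu = pv[PV_NU]
    l1s = 2.0 * aa * aa
    d1s = 2.0 * bb * bb
    e1 = l1s - d1s
    f1 = l1s + d1s
    goxx = e1 * co * co + d1s
    goyy = e1 * so * so + d1s
    goxy = e1 * co * so
    gnxx = e1 * cn * cn + d1s
    gnyy = e1 * sn * sn + d1s
    gnxy = e1 * cn * sn
    tot = 0.0
    for idx in range(nnbr[i]):
        j = nbr[i, idx]
        cj = cphi[j]
        sj = sphi[j]
        aj = a[j]
        bj = b[j]
        l2s = 2.0 * aj * aj
        d2s = 2.0 * bj * bj
        e2 = l2s - d2s
        f2 = l2s + d2s
        g2xx = e2 * cj * cj + d2s
        g2yy = e2 * sj * sj + d2s
        g2xy = e2 * cj * sj
        dx = x[j] - xi
        if dx >= hL:
            dx -= L
        elif dx < -hL:
            dx += L
        dy = y[j] - yi
        if dy >= hL:
            dy -= L
        elif dy < -hL:
            dy += L
        r2 = dx * dx + dy * dy
        if r2 < 1e-24:
            r2 = 1e-24
        al = dx * co + dy * so
        pe = -dx * so + dy * co
        if al * al * inv_am2 + pe * pe * inv_bm2 <= 1.0:
            tot -= _gb_core(dx, dy, r2, goxx + g2xx, goyy + g2yy, goxy + g2xy,
                            e1, f1, d1s, e2, f2, d2s,
                            co * cj + so * sj, eps0, mu, nu)
        al = dx * cn + dy * sn
        pe = -dx * sn + dy * cn
        if al * al * inv_am2 + pe * pe * inv_bm2 <= 1.0:
            tot += _gb_core(dx, dy, r2, gnxx + g2xx, gnyy + g2yy, gnxy + g2xy,
                            e1, f1, d1s, e2, f2, d2s,
                            cn * cj + sn * sj, eps0, mu, nu)
    return tot


@njit(cache=True, fastmath=True, inline="always")
def k_pair_delta_resize(i, xi, yi, c, s, ao, bo, an, bn,
                        x, y, a, b, cphi, sphi, nbr, nnbr, pv):
    L = pv[PV_L]
    hL = 0.5 * L
    inv_am2 = 1.0 / (pv[PV_RC_MAJ] * pv[PV_RC_MAJ])
    inv_bm2 = 1.0 / (pv[PV_RC_MIN] * pv[PV_RC_MIN])
    eps0 = pv[PV_EPS0]
    mu = pv[PV_MU]
    nu = pv[PV_NU]
    l1so = 2.0 * ao * ao
    d1so = 2.0 * bo * bo
    e1o = l1so - d1so
    f1o = l1so + d1so
    l1sn = 2.0 * an * an
    d1sn = 2.0 * bn * bn
    e1n = l1sn - d1sn
    f1n = l1sn + d1sn
    goxx = e1o * c * c + d1so
    goyy = e1o * s * s + d1so
    goxy = e1o * c * s
    gnxx = e1n * c * c + d1sn
    gnyy = e1n * s * s + d1sn
    gnxy = e1n * c * s
    tot = 0.0
    for idx in range(nnbr[i]):
        j = nbr[i, idx]
        cj = cphi[j]
        sj = sphi[j]
        aj = a[j]
        bj = b[j]
        dx = x[j] - xi
        if dx >= hL:
            dx -= L
        elif dx < -hL:
            dx += L
        dy = y[j] - yi
        if dy >= hL:
            dy -= L
        elif dy < -hL:
            dy += L
        al = dx * c + dy * s
        pe = -dx * s + dy * c
        # position and orientation are unchanged: one shared cutoff test
        if al * al * inv_am2 + pe * pe * inv_bm2 > 1.0:
            continue
        r2 = dx * dx + dy * dy
        if r2 < 1e-24:
            r2 = 1e-24
        l2s = 2.0 * aj * aj
        d2s = 2.0 * bj * bj
        e2 = l2s - d2s
        f2 = l2s + d2s
        g2xx = e2 * cj * cj + d2s
        g2yy = e2 * sj * sj + d2s
        g2xy = e2 * cj * sj
        dot = c * cj + s * sj
        tot -= _gb_core(dx, dy, r2, goxx + g2xx, goyy + g2yy, goxy + g2xy,
                        e1o, f1o, d1so, e2, f2, d2s, dot, eps0, mu, nu)
        tot += _gb_core(dx, dy, r2, gnxx + g2xx, gnyy + g2yy, gnxy + g2xy,
                        e1n, f1n, d1sn, e2, f2, d2s, dot, eps0, mu, nu)
    return tot


@njit(cache=True)
def k_local_energy(i, x, y, a, b, cphi, sphi, nbr, nnbr, fsx, fsy, pv):
    """Full local energy of cell i (shape + core + ridge + pair sum)."""
    ci = cphi[i]
    si = sphi[i]
    e = k_shape_core(a[i], b[i], pv[PV_A_PREF], pv[PV_AR_PREF],
                     pv[PV_K_A], pv[PV_K_AR], pv[PV_K_CORE])
    e += pv[PV_K_R] * k_upsilon(x[i], y[i], a[i], b[i], ci, si, fsx, fsy,
                                pv[PV_PCX], pv[PV_PCY], pv[PV_L],
                                pv[PV_SPACING], pv[PV_HALF_WIDTH], pv[PV_KMAX])
    L = pv[PV_L]
    inv_am2 = 1.0 / (pv[PV_RC_MAJ] * pv[PV_RC_MAJ])
    inv_bm2 = 1.0 / (pv[PV_RC_MIN] * pv[PV_RC_MIN])
    for idx in range(nnbr[i]):
        j = nbr[i, idx]
        dx = k_wrap(x[j] - x[i], L)
        dy = k_wrap(y[j] - y[i], L)
        if k_in_cutoff(dx, dy, ci, si, inv_am2, inv_bm2):
            e += k_pair_u(dx, dy, a[i], b[i], ci, si,
                          a[j], b[j], cphi[j], sphi[j],
                          pv[PV_EPS0], pv[PV_MU], pv[PV_NU])
    return e


# --------------------------------------------------------------------------
# division
# --------------------------------------------------------------------------

@njit(cache=True)
def k_divide(rng, meta, x, y, a, b, phi, cphi, sphi, px, py, ids, parent,
             wbuf, pv):
    """One division event: weighted parent choice, two daughters.

    Daughters keep the parent's orientation and 0.4x axes, placed at
    +-0.4 a along the major axis; the parent's slot becomes daughter 1
    and daughter 2 is appended. Returns the parent's array index.
    """
    n = int(meta[META_N])
    A_pref = pv[PV_A_PREF]
    AR_pref = pv[PV_AR_PREF]
    alpha = pv[PV_ALPHA]
    if pv[PV_DIV_MODE] == 1.0:
        isel = rand_below(rng, n)
    else:
        m = -1.0e300
        for i in range(n):
            w = math.pi * a[i] * b[i] / A_pref - alpha * (a[i] / b[i]) / AR_pref
            wbuf[i] = w
            if w > m:
                m = w
        tot = 0.0
        for i in range(n):
            wbuf[i] = math.exp(wbuf[i] - m)
            tot += wbuf[i]
        u = uniform(rng) * tot
        acc = 0.0
        isel = n - 1
        for i in range(n):
            acc += wbuf[i]
            if u < acc:
                isel = i
                break
    L = pv[PV_L]
    f = pv[PV_DAUGHTER_F]
    c = cphi[isel]
    s = sphi[isel]
    off = f * a[isel]
    old_id = ids[isel]
    x1 = k_wrap_pos(x[isel] + off * c, L)
    y1 = k_wrap_pos(y[isel] + off * s, L)
    x2 = k_wrap_pos(x[isel] - off * c, L)
    y2 = k_wrap_pos(y[isel] - off * s, L)
    a_d = f * a[isel]
    b_d = f * b[isel]
    # daughter 1 replaces the parent slot
    x[isel] = x1
    y[isel] = y1
    a[isel] = a_d
    b[isel] = b_d
    ids[isel] = meta[META_NEXT_ID]
    meta[META_NEXT_ID] += 1
    parent[isel] = old_id
    # daughter 2 appended
    x[n] = x2
    y[n] = y2
    a[n] = a_d
    b[n] = b_d
    phi[n] = phi[isel]
    cphi[n] = c
    sphi[n] = s
    ids[n] = meta[META_NEXT_ID]
    meta[META_NEXT_ID] += 1
    parent[n] = old_id
    if pv[PV_DAUGHTER_POL] == 1.0:
        th1 = 2.0 * math.pi * uniform(rng)
        th2 = 2.0 * math.pi * uniform(rng)
        px[isel] = math.cos(th1)
        py[isel] = math.sin(th1)
        px[n] = math.cos(th2)
        py[n] = math.sin(th2)
    else:
        px[n] = px[isel]
        py[n] = py[isel]
    meta[META_N] = n + 1
    return isel


# --------------------------------------------------------------------------
# the fused sweep kernel
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_block(rng, meta, x, y, a, b, phi, cphi, sphi, px, py, ids, parent,
              nbr, nnbr, moved, rotm, ridge_cache, perm, dxr, dyr, wbuf,
              fsx, fsy, pv, n_mcs, counters):
    """Advance the simulation by ``n_mcs`` Monte Carlo steps.

    One MCS = one proposed move per cell in a fresh random order,
    followed by per-cell polarity feedback; at flip-period boundaries
    polarity reversals, then (growth phase) one division. ``counters``
    accumulates proposed/accepted tallies per move kind (0 displace,
    1 rotate, 2 resize-a, 3 resize-b).

    List maintenance: accepted displacements accumulate in ``moved``
    and trigger a full rebuild past half the skin; accepted rotations
    accumulate ``rc_maj * |dphi|`` in ``rotm`` and trigger an O(N)
    refresh of the rotating cell's own row only (its orientation enters
    no other list). Divisions always trigger a full rebuild.
    """
    L = pv[PV_L]
    T = pv[PV_T]
    k_move = pv[PV_K_MOVE]
    skin = pv[PV_SKIN]
    rc_maj = pv[PV_RC_MAJ]
    rc_min = pv[PV_RC_MIN]
    pcx = pv[PV_PCX]
    pcy = pv[PV_PCY]
    spacing = pv[PV_SPACING]
    half_w = pv[PV_HALF_WIDTH]
    kmax = pv[PV_KMAX]
    k_r = pv[PV_K_R]
    tau_pol = pv[PV_TAU_POL]
    pol_keep = 1.0 - 1.0 / tau_pol
    flip_period = int(pv[PV_FLIP_PERIOD])
    flip_prob = pv[PV_FLIP_PROB]
    div_period = int(pv[PV_DIV_PERIOD])
    relax_mcs = int(pv[PV_RELAX_MCS])
    terminal = int(pv[PV_TERMINAL])
    growth_on = pv[PV_GROWTH_ON] == 1.0
    feedback_proposed = pv[PV_POL_FEEDBACK] == 1.0

    for _ in range(n_mcs):
        n = int(meta[META_N])
        for i in range(n):
            perm[i] = i
            dxr[i] = 0.0
            dyr[i] = 0.0
        # Fisher–Yates, descending index
        for i in range(n - 1, 0, -1):
            j = rand_below(rng, i + 1)
            t = perm[i]
            perm[i] = perm[j]
            perm[j] = t
        for kk in range(n):
            i = perm[kk]
            kind = k_draw_kind(rng, pv[PV_MIX0], pv[PV_MIX1], pv[PV_MIX2])
            counters[kind] += 1
            ci = cphi[i]
            si = sphi[i]
            if kind == 0:
                # displacement
                mag = pv[PV_DELTA_R] * uniform(rng)
                psi = 2.0 * math.pi * uniform(rng)
                dx = mag * math.cos(psi)
                dy = mag * math.sin(psi)
                if feedback_proposed:
                    dxr[i] = dx
                    dyr[i] = dy
                xn = k_wrap_pos(x[i] + dx, L)
                yn = k_wrap_pos(y[i] + dy, L)
                ups_new = k_upsilon(xn, yn, a[i], b[i], ci, si, fsx, fsy,
                                    pcx, pcy, L, spacing, half_w, kmax)
                dE = k_r * ups_new - ridge_cache[i]
                dE += k_pair_delta_displace(i, x[i], y[i], xn, yn, ci, si,
                                            a[i], b[i], x, y, a, b,
                                            cphi, sphi, nbr, nnbr, pv)
                udotp = ci * px[i] + si * py[i]
                if udotp > 0.0:
                    dE -= k_move * (ci * dx + si * dy)
                elif udotp < 0.0:
                    dE += k_move * (ci * dx + si * dy)
                if k_metro_accept(rng, dE, T):
                    counters[4] += 1
                    x[i] = xn
                    y[i] = yn
                    ridge_cache[i] = k_r * ups_new
                    if not feedback_proposed:
                        dxr[i] = dx
                        dyr[i] = dy
                    moved[i] += math.sqrt(dx * dx + dy * dy)
                    if moved[i] > TRIG_FRAC * skin:
                        st = k_build_lists(x, y, cphi, sphi, n, nbr, nnbr,
                                           moved, rotm, L, rc_maj, rc_min,
                                           skin)
                        if st != STATUS_OK:
                            return st
            elif kind == 1:
                # rotation (polarity co-rotates on acceptance)
                dphi = 2.0 * pv[PV_DELTA_PHI] * (uniform(rng) - 0.5)
                phin = phi[i] + dphi
                phin -= 2.0 * math.pi * math.floor(phin / (2.0 * math.pi))
                cn = math.cos(phin)
                sn = math.sin(phin)
                ups_new = k_upsilon(x[i], y[i], a[i], b[i], cn, sn, fsx, fsy,
                                    pcx, pcy, L, spacing, half_w, kmax)
                dE = k_r * ups_new - ridge_cache[i]
                dE += k_pair_delta_rotate(i, x[i], y[i], ci, si, cn, sn,
                                          a[i], b[i], x, y, a, b,
                                          cphi, sphi, nbr, nnbr, pv)
                if k_metro_accept(rng, dE, T):
                    counters[5] += 1
                    phi[i] = phin
                    cphi[i] = cn
                    sphi[i] = sn
                    ridge_cache[i] = k_r * ups_new
                    cd = math.cos(dphi)
                    sd = math.sin(dphi)
                    pxn = cd * px[i] - sd * py[i]
                    pyn = sd * px[i] + cd * py[i]
                    px[i] = pxn
                    py[i] = pyn
                    rotm[i] += rc_maj * abs(dphi)
                    if rotm[i] > TRIG_FRAC * skin:
                        st = k_build_row(i, x, y, cphi, sphi, n, nbr, nnbr,
                                         rotm, L, rc_maj, rc_min, skin)
                        if st != STATUS_OK:
                            return st
            else:
                # axis resize; invalid shapes rejected outright
                if kind == 2:
                    da = pv[PV_DELTA_A] * (uniform(rng) - 0.5)
                    an = a[i] + da
                    bn = b[i]
                    if an < bn:
                        continue
                else:
                    db = pv[PV_DELTA_B] * (uniform(rng) - 0.5)
                    an = a[i]
                    bn = b[i] + db
                    if bn <= 0.0 or an < bn:
                        continue
                dE = (k_shape_core(an, bn, pv[PV_A_PREF], pv[PV_AR_PREF],
                                   pv[PV_K_A], pv[PV_K_AR], pv[PV_K_CORE])
                      - k_shape_core(a[i], b[i], pv[PV_A_PREF], pv[PV_AR_PREF],
                                     pv[PV_K_A], pv[PV_K_AR], pv[PV_K_CORE]))
                ups_new = k_upsilon(x[i], y[i], an, bn, ci, si, fsx, fsy,
                                    pcx, pcy, L, spacing, half_w, kmax)
                dE += k_r * ups_new - ridge_cache[i]
                dE += k_pair_delta_resize(i, x[i], y[i], ci, si,
                                          a[i], b[i], an, bn, x, y, a, b,
                                          cphi, sphi, nbr, nnbr, pv)
                if k_metro_accept(rng, dE, T):
                    counters[4 + kind] += 1
                    a[i] = an
                    b[i] = bn
                    ridge_cache[i] = k_r * ups_new
        # polarity feedback from this MCS's realized displacement
        for i in range(n):
            px[i] = pol_keep * px[i] + dxr[i]
            py[i] = pol_keep * py[i] + dyr[i]
        meta[META_MCS] += 1
        mcs = int(meta[META_MCS])
        if mcs % flip_period == 0:
            for i in range(n):
                if uniform(rng) < flip_prob:
                    px[i] = -px[i]
                    py[i] = -py[i]
        if growth_on and mcs % div_period == 0 and mcs >= relax_mcs \
                and int(meta[META_N]) < terminal:
            isel = k_divide(rng, meta, x, y, a, b, phi, cphi, sphi,
                            px, py, ids, parent, wbuf, pv)
            n = int(meta[META_N])
            st = k_build_lists(x, y, cphi, sphi, n, nbr, nnbr, moved, rotm,
                               L, rc_maj, rc_min, skin)
            if st != STATUS_OK:
                return st
            ridge_cache[isel] = k_r * k_upsilon(
                x[isel], y[isel], a[isel], b[isel], cphi[isel], sphi[isel],
                fsx, fsy, pcx, pcy, L, spacing, half_w, kmax)
            ridge_cache[n - 1] = k_r * k_upsilon(
                x[n - 1], y[n - 1], a[n - 1], b[n - 1], cphi[n - 1], sphi[n - 1],
                fsx, fsy, pcx, pcy, L, spacing, half_w, kmax)
            dxr[n - 1] = 0.0
            dyr[n - 1] = 0.0
    return STATUS_OK


# --------------------------------------------------------------------------
# small sampling helpers (acceptance targets, closed-form checks)
# --------------------------------------------------------------------------

@njit(cache=True)
def tally_proposal_kinds(rng, n, m0, m1, m2):
    """Draw n move kinds with the engine's selector; return the tallies."""
    counts = np.zeros(4, dtype=np.int64)
    for _ in range(n):
        counts[k_draw_kind(rng, m0, m1, m2)] += 1
    return counts


@njit(cache=True)
def mean_flip_wait_checks(rng, flip_prob, n_events):
    """Mean number of per-period reversal checks between flips.

    Runs the engine's per-check Bernoulli draw until ``n_events`` flips
    have occurred and returns the average waiting time in checks.
    """
    total = 0
    events = 0
    wait = 0
    while events < n_events:
        wait += 1
        if uniform(rng) < flip_prob:
            total += wait
            events += 1
            wait = 0
    return total / n_events


@njit(cache=True)
def metro_accept_fraction(rng, dE, T, n):
    """Empirical acceptance fraction of a fixed-dE Metropolis decision."""
    acc = 0
    for _ in range(n):
        if k_metro_accept(rng, dE, T):
            acc += 1
    return acc / n
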