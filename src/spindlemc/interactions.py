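"""Anisotropic cell–cell interaction: a modified Gay–Berne potential.

Pairs of elliptical cells interact through a 12-6 potential evaluated at
a scaled, shifted separation

    U = 4 eps (r^-12 - r^-6),   r = (|r12| - sigma + sigma0) / sigma0,

where the contact scale ``sigma`` depends on both cells' sizes and
orientations through the overlap matrices

    gamma_i = (l_i^2 - d_i^2) u_i u_i^T + d_i^2 I,
    sigma   = (rhat^T (gamma_1 + gamma_2)^{-1} rhat)^{-1/2},

with ``l_i = sqrt(2) a_i`` and ``d_i = sqrt(2) b_i``, and
``sigma0 = sqrt(2 b_1^2 + 2 b_2^2)`` the side-by-side contact scale of
the circular limit. The well depth is

    eps = eps0 * eps_a^nu * eps_b^mu,
    eps_a = [1 - chi^2 (u1.u2)^2]^{-1/2},   eps_b = (sigma0 / sigma)^2,

which favors parallel, side-by-side packing of elongated cells — the
nematic ordering mechanism of the model. ``eps_b`` is taken in the
dimensionless convention (equal to 1 for circular cells), so the
isotropic limit reduces exactly to a plain 12-6 potential of strength
``eps0`` and contact scale ``2b``.

Interaction range is truncated by an *elliptical, one-sided* cutoff: the
energy of cell ``i`` sums over cells whose centers fall inside an
ellipse of semi-axes ``(rc_maj, rc_min)`` centered on ``i`` and oriented
along ``i``'s major axis. The pair function itself is symmetric; the
cutoff is not, which is a deliberate model property (no global symmetric
Hamiltonian exists — the Metropolis dynamics are still well defined).

These are pure numpy reference implementations; the compiled engine
re-derives the same quantities and is cross-checked against this module
to 1e-9 relative tolerance in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Cell, ModelParams, SimState, minimum_image

__all__ = [
    "PairGeometry",
    "shape_matrix",
    "anisotropy_chi",
    "range_sigma",
    "strength_epsilon",
    "pair_energy",
    "in_interaction_cutoff",
    "build_neighbor_lists",
    "SCALED_DISTANCE_FLOOR",
]

#: Floor applied to the scaled distance r to keep the energy finite for
#: (transiently) near-coincident centers; Metropolis then near-surely
#: rejects the configuration.
SCALED_DISTANCE_FLOOR = 1e-3

_SQRT2 = np.sqrt(2.0)


@dataclass
class PairGeometry:
    """Geometric ingredients of one pair interaction."""

    u1: np.ndarray
    u2: np.ndarray
    r12: np.ndarray          # minimum-image center-to-center vector, μm
    l1: float
    d1: float
    l2: float
    d2: float

    @classmethod
    def from_cells(cls, cell1: Cell, cell2: Cell, L: float) -> "PairGeometry":
        r12 = minimum_image(cell1.center - cell2.center, L)
        return cls(
            u1=cell1.u, u2=cell2.u, r12=r12,
            l1=_SQRT2 * cell1.a, d1=_SQRT2 * cell1.b,
            l2=_SQRT2 * cell2.a, d2=_SQRT2 * cell2.b,
        )

    @property
    def r12_hat(self) -> np.ndarray:
        norm = np.hypot(*self.r12)
        if norm == 0.0:
            raise ZeroDivisionError("coincident cell centers have no direction")
        return self.r12 / norm

    @property
    def sigma0(self) -> float:
        return float(np.sqrt(self.d1 ** 2 + self.d2 ** 2))


def shape_matrix(cell: Cell) -> np.ndarray:
    """Overlap matrix ``gamma = (l^2 - d^2) u u^T + d^2 I`` (μm²).

    Symmetric positive definite with eigenvalues ``l^2`` along the major
    axis and ``d^2`` perpendicular to it.
    """
    u = cell.u
    l2 = 2.0 * cell.a ** 2
    d2 = 2.0 * cell.b ** 2
    return (l2 - d2) * np.outer(u, u) + d2 * np.eye(2)


def anisotropy_chi(cell1: Cell, cell2: Cell) -> float:
    """Shape-anisotropy parameter chi in [0, 1)."""
    l1s, d1s = 2.0 * cell1.a ** 2, 2.0 * cell1.b ** 2
    l2s, d2s = 2.0 * cell2.a ** 2, 2.0 * cell2.b ** 2
    num = (l1s - d1s) * (l2s - d2s)
    den = (l1s + d1s) * (l2s + d2s)
    return float(np.sqrt(num / den))


def range_sigma(pair: PairGeometry) -> float:
    """Anisotropic contact scale sigma = (rhat^T gamma^{-1} rhat)^{-1/2}."""
    u1, u2 = pair.u1, pair.u2
    g = ((pair.l1 ** 2 - pair.d1 ** 2) * np.outer(u1, u1) + pair.d1 ** 2 * np.eye(2)
         + (pair.l2 ** 2 - pair.d2 ** 2) * np.outer(u2, u2) + pair.d2 ** 2 * np.eye(2))
    rhat = pair.r12_hat
    q = float(rhat @ np.linalg.solve(g, rhat))
    return 1.0 / np.sqrt(q)


def strength_epsilon(pair: PairGeometry, params: ModelParams) -> float:
    """Orientation- and shape-dependent well depth eps."""
    chi2 = ((pair.l1 ** 2 - pair.d1 ** 2) * (pair.l2 ** 2 - pair.d2 ** 2)
            / ((pair.l1 ** 2 + pair.d1 ** 2) * (pair.l2 ** 2 + pair.d2 ** 2)))
    dot = float(pair.u1 @ pair.u2)
    eps_a = 1.0 / np.sqrt(1.0 - chi2 * dot * dot)
    eps_b = (pair.sigma0 / range_sigma(pair)) ** 2
    return params.eps0 * eps_a ** params.nu * eps_b ** params.mu


def pair_energy(cell1: Cell, cell2: Cell, L: float, params: ModelParams) -> float:
    """Gay–Berne 12-6 energy of one pair (no cutoff applied here).

    Zero at ``|r12| = sigma``; minimum ``-eps`` at scaled distance
    ``2^(1/6)``; diverges repulsively as the scaled distance tends to 0
    (floored at :data:`SCALED_DISTANCE_FLOOR` to stay finite for
    coincident centers).
    """
    pair = PairGeometry.from_cells(cell1, cell2, L)
    dist = float(np.hypot(*pair.r12))
    if dist == 0.0:
        r = SCALED_DISTANCE_FLOOR
        # orientation undefined; use the isotropic well depth
        eps = params.eps0
    else:
        sigma = range_sigma(pair)
        r = (dist - sigma + pair.sigma0) / pair.sigma0
        r = max(r, SCALED_DISTANCE_FLOOR)
        eps = strength_epsilon(pair, params)
    inv6 = r ** -6
    return 4.0 * eps * (inv6 * inv6 - inv6)


def in_interaction_cutoff(cell_i: Cell, cell_j: Cell, L: float,
                          params: ModelParams, pad: float = 0.0) -> bool:
    """Whether ``j``'s center lies in the cutoff ellipse of ``i``.

    The ellipse is centered on ``i``, oriented along ``i``'s major axis,
    with semi-axes ``(rc_maj + pad, rc_min + pad)``. Note the asymmetry:
    this depends on ``i``'s orientation only.
    """
    d = minimum_image(cell_j.center - cell_i.center, L)
    u = cell_i.u
    along = float(d @ u)
    perp = float(d[0] * -u[1] + d[1] * u[0])
    am = params.rc_maj + pad
    bm = params.rc_min + pad
    return (along / am) ** 2 + (perp / bm) ** 2 <= 1.0


def build_neighbor_lists(state: SimState) -> list:
    """Brute-force O(N²) neighbor lists for the current state.

    Cell ``i``'s list holds the *indices* ``j != i`` whose centers lie
    inside ``i``'s cutoff ellipse padded by the skin. This is the
    reference the compiled engine's list builder is validated against;
    the engine applies the exact (unpadded) cutoff again at energy
    evaluation time, so padding only ever adds candidates.
    """
    cells = state.cells()
    params = state.params
    out = []
    for i, ci in enumerate(cells):
        lst = [
            j for j, cj in enumerate(cells)
            if j != i and in_interaction_cutoff(ci, cj, params.L, params,
                                                pad=params.skin)
        ]
        out.append(lst)
    return out
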