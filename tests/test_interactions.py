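"""Gay–Berne pair potential, cutoff, and neighbor lists."""

import math

import numpy as np
import pytest

import spindlemc._kernels as K
from spindlemc import (
    Cell,
    ModelParams,
    anisotropy_chi,
    build_neighbor_lists,
    in_interaction_cutoff,
    initialize_state,
    pair_energy,
    range_sigma,
    shape_matrix,
    strength_epsilon,
)
from spindlemc.interactions import PairGeometry
from conftest import rand_cells


def _cell(a, b, phi=0.0, center=(0.0, 0.0)):
    return Cell(id=0, center=np.array(center, float), a=a, b=b, phi=phi,
                polarity=np.zeros(2))


def _pair(c1, c2, L=1200.0):
    return PairGeometry.from_cells(c1, c2, L)


# --------------------------------------------------------------------------
# shape matrix and anisotropy
# --------------------------------------------------------------------------

def test_shape_matrix_eigenstructure():
    circ = shape_matrix(_cell(10.0, 10.0))
    assert np.allclose(circ, 200.0 * np.eye(2))   # d^2 = 2 b^2

    g = shape_matrix(_cell(40.0, 10.0, phi=0.0))
    assert np.allclose(g, np.diag([3200.0, 200.0]))

    theta = 0.77
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    g_rot = shape_matrix(_cell(40.0, 10.0, phi=theta))
    assert np.allclose(g_rot, rot @ np.diag([3200.0, 200.0]) @ rot.T)


def test_chi_limits_and_symmetry():
    assert anisotropy_chi(_cell(10, 10), _cell(25, 25)) == 0.0
    c1, c2 = _cell(40, 10), _cell(40, 10)
    assert anisotropy_chi(c1, c2) == pytest.approx(15.0 / 17.0, rel=1e-12)
    a, b = _cell(33, 12), _cell(50, 11)
    assert anisotropy_chi(a, b) == anisotropy_chi(b, a)
    assert 0.0 <= anisotropy_chi(a, b) < 1.0


# --------------------------------------------------------------------------
# range and strength
# --------------------------------------------------------------------------

def test_sigma_circular_limit_is_contact_diameter():
    c1 = _cell(10.0, 10.0)
    c2 = _cell(10.0, 10.0, center=(37.0, 11.0))
    pair = _pair(c1, c2)
    assert range_sigma(pair) == pytest.approx(20.0, rel=1e-12)
    assert pair.sigma0 == pytest.approx(20.0, rel=1e-12)


def test_sigma_parallel_end_to_end_and_side_by_side():
    a, b = 40.0, 10.0
    c1 = _cell(a, b, phi=0.0)
    end = _cell(a, b, phi=0.0, center=(90.0, 0.0))
    side = _cell(a, b, phi=0.0, center=(0.0, 25.0))
    assert range_sigma(_pair(c1, end)) == pytest.approx(2 * a, rel=1e-12)
    assert range_sigma(_pair(c1, side)) == pytest.approx(2 * b, rel=1e-12)


def test_epsilon_isotropic_limit_and_symmetry(default_params):
    p = default_params
    c1 = _cell(10.0, 10.0)
    c2 = _cell(10.0, 10.0, center=(30.0, 5.0))
    assert strength_epsilon(_pair(c1, c2), p) == pytest.approx(p.eps0, rel=1e-12)

    e1 = _cell(38, 11, phi=0.4)
    e2 = _cell(44, 9, phi=1.9, center=(40.0, 20.0))
    eps_12 = strength_epsilon(_pair(e1, e2), p)
    eps_21 = strength_epsilon(_pair(e2, e1), p)
    assert eps_12 == pytest.approx(eps_21, rel=1e-12)
    assert eps_12 > 0


def test_epsilon_side_by_side_formula(default_params):
    p = default_params
    a, b = 40.0, 10.0
    c1 = _cell(a, b, phi=0.0)
    c2 = _cell(a, b, phi=0.0, center=(0.0, 25.0))
    pair = _pair(c1, c2)
    chi2 = (15.0 / 17.0) ** 2
    eps_a = 1.0 / math.sqrt(1.0 - chi2)
    eps_b = (pair.sigma0 / (2 * b)) ** 2      # sigma = 2b side-by-side
    assert strength_epsilon(pair, p) == pytest.approx(
        p.eps0 * eps_a * eps_b, rel=1e-12)


# --------------------------------------------------------------------------
# pair energy
# --------------------------------------------------------------------------

def test_pair_energy_zero_at_contact_and_minimum_depth(default_params):
    p = default_params
    a, b = 40.0, 10.0
    c1 = _cell(a, b, phi=0.0)
    # side-by-side: sigma = 2b = 20, sigma0 = 20
    at_contact = _cell(a, b, phi=0.0, center=(0.0, 20.0))
    assert pair_energy(c1, at_contact, p.L, p) == pytest.approx(0.0, abs=1e-12)

    # scaled distance 2^(1/6): |r12| = sigma + (2^(1/6)-1) sigma0
    d = 20.0 + (2 ** (1 / 6) - 1) * 20.0
    at_min = _cell(a, b, phi=0.0, center=(0.0, d))
    eps = strength_epsilon(_pair(c1, at_min), p)
    assert pair_energy(c1, at_min, p.L, p) == pytest.approx(-eps, rel=1e-9)


def test_parallel_side_by_side_is_preferred_configuration(default_params):
    """Nematic packing: at equal scaled distance, side-by-side parallel
    beats T and end-to-end configurations."""
    p = default_params
    a, b = 40.0, 10.0
    r_scaled = 2 ** (1 / 6)

    def energy(phi2, direction):
        c1 = _cell(a, b, phi=0.0)
        probe = _cell(a, b, phi=phi2, center=(direction[0], direction[1]))
        pair = _pair(c1, probe)
        sigma = range_sigma(pair)
        dist = sigma + (r_scaled - 1) * pair.sigma0
        c2 = _cell(a, b, phi=phi2,
                   center=(dist * direction[0], dist * direction[1]))
        return pair_energy(c1, c2, p.L, p)

    side = energy(0.0, (0.0, 1.0))
    tee = energy(math.pi / 2, (1.0, 0.0))
    end = energy(0.0, (1.0, 0.0))
    assert side < tee and side < end
    assert side == pytest.approx(-strength_epsilon(
        _pair(_cell(a, b), _cell(a, b, center=(0.0, 25.0))), p), rel=1e-6)


def test_pair_energy_symmetric_and_repulsive_core(default_params):
    p = default_params
    rng = np.random.default_rng(7)
    for c1, c2 in zip(rand_cells(20, p.L, rng), rand_cells(20, p.L, rng)):
        assert pair_energy(c1, c2, p.L, p) == pytest.approx(
            pair_energy(c2, c1, p.L, p), rel=1e-9, abs=1e-12)
    # close approach is strongly repulsive
    c1 = _cell(40, 10)
    c2 = _cell(40, 10, center=(0.0, 4.0))
    assert pair_energy(c1, c2, p.L, p) > 1e3


def test_single_minimum_and_sign_change_along_separation(default_params):
    p = default_params
    c1 = _cell(40.0, 10.0, phi=0.3)
    distances = np.linspace(14.0, 95.0, 400)
    u = np.array([math.cos(1.1), math.sin(1.1)])
    e = [pair_energy(c1, _cell(40.0, 10.0, phi=0.3, center=tuple(d * u)),
                     p.L, p) for d in distances]
    e = np.array(e)
    signs = np.sign(e[np.abs(e) > 1e-12])
    flips = np.count_nonzero(np.diff(signs))
    assert flips == 1
    k = int(np.argmin(e))
    assert 0 < k < len(e) - 1
    assert np.all(np.diff(e[:k + 1]) <= 1e-12)
    assert np.all(np.diff(e[k:]) >= -1e-12)


def test_circular_cells_reduce_to_isotropic_12_6(default_params):
    """Closed-form oracle: circular cells give a plain 12-6 potential
    with contact scale 2b."""
    p = default_params
    b1, b2 = 10.0, 14.0
    sigma0 = math.sqrt(2 * b1 ** 2 + 2 * b2 ** 2)
    for dist in (22.0, 28.0, 40.0, 75.0):
        c1 = _cell(b1, b1)
        c2 = _cell(b2, b2, center=(dist, 0.0))
        r = (dist - sigma0 + sigma0) / sigma0
        expected = 4 * p.eps0 * (r ** -12 - r ** -6)
        assert pair_energy(c1, c2, p.L, p) == pytest.approx(expected, rel=1e-12)


def test_kernel_pair_energy_matches_reference_on_random_configs(default_params):
    """Compiled energy vs the independent numpy implementation,
    1e-9 relative tolerance on 1000 random configurations."""
    p = default_params
    rng = np.random.default_rng(42)
    cells = rand_cells(2000, p.L, rng)
    worst = 0.0
    for k in range(1000):
        c1, c2 = cells[2 * k], cells[2 * k + 1]
        ref = pair_energy(c1, c2, p.L, p)
        d = c1.center - c2.center
        d -= p.L * np.floor(d / p.L + 0.5)
        got = K.k_pair_u(d[0], d[1], c1.a, c1.b,
                         math.cos(c1.phi), math.sin(c1.phi),
                         c2.a, c2.b, math.cos(c2.phi), math.sin(c2.phi),
                         p.eps0, p.mu, p.nu)
        err = abs(got - ref) / max(abs(ref), 1e-300)
        worst = max(worst, err)
    assert worst < 1e-9


# --------------------------------------------------------------------------
# cutoff and neighbor lists
# --------------------------------------------------------------------------

def test_cutoff_ellipse_membership(default_params):
    p = default_params
    me = _cell(40.0, 10.0, phi=0.0, center=(600.0, 600.0))

    def at(dx, dy):
        return _cell(10, 10, center=(600.0 + dx, 600.0 + dy))

    assert in_interaction_cutoff(me, at(0, 0), p.L, p)
    assert in_interaction_cutoff(me, at(99.0, 0.0), p.L, p)
    assert not in_interaction_cutoff(me, at(101.0, 0.0), p.L, p)
    assert not in_interaction_cutoff(me, at(0.0, 44.0), p.L, p)
    # rotating the observer rotates the ellipse
    rot = _cell(40.0, 10.0, phi=math.pi / 2, center=(600.0, 600.0))
    assert in_interaction_cutoff(rot, at(0.0, 99.0), p.L, p)
    assert not in_interaction_cutoff(rot, at(99.0, 0.0), p.L, p)


def test_neighbor_lists_match_bruteforce_oracle():
    params = ModelParams(L=600.0, n_init=50, terminal_count=60,
                         relax_time=0.0).validate()
    state = initialize_state(params, seed=11)
    oracle = build_neighbor_lists(state)
    for i in range(state.n):
        got = sorted(int(j) for j in state.nbr[i, :state.nnbr[i]])
        padded = set(oracle[i])
        exact = {
            j for j in range(state.n) if j != i and in_interaction_cutoff(
                state.cell(i), state.cell(j), params.L, params)
        }
        # every interacting pair is listed; every listed pair is within
        # the skin-padded cutoff
        assert exact <= set(got)
        assert set(got) <= padded


def test_neighbor_lists_trivial_cases():
    params = ModelParams(L=1200.0, n_init=1, terminal_count=4,
                         relax_time=0.0).validate()
    s = initialize_state(params, seed=1)
    assert s.nnbr[0] == 0
    params2 = ModelParams(L=1200.0, n_init=2, terminal_count=4,
                          relax_time=0.0).validate()
    for seed in range(2, 30):
        s2 = initialize_state(params2, seed=seed)
        d = np.hypot(*(np.array([s2.x[0] - s2.x[1], s2.y[0] - s2.y[1]])))
        if d > 400.0:   # far beyond any cutoff
            assert s2.nnbr[0] == 0 and s2.nnbr[1] == 0
            break
    else:
        pytest.skip("no well-separated random placement found")


def test_neighbor_lists_never_miss_interacting_pairs_during_dynamics():
    """Stress the skin policy: after many accepted moves, every pair
    within (cutoff − skin) appears in the list."""
    from spindlemc import run_mcs
    from spindlemc.dynamics import ensure_engine

    params = ModelParams(L=400.0, n_init=30, terminal_count=40,
                         relax_time=0.0).validate()
    state = initialize_state(params, seed=5)
    ensure_engine(state)
    for _ in range(6):
        run_mcs(state, 50)
        cells = state.cells()
        for i in range(state.n):
            listed = set(int(j) for j in state.nbr[i, :state.nnbr[i]])
            for j in range(state.n):
                if j == i:
                    continue
                inner = in_interaction_cutoff(cells[i], cells[j], params.L,
                                              params, pad=-params.skin)
                if inner:
                    assert j in listed, (i, j, state.mcs)
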