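"""Alignment, radial profiles, velocity histograms, ridge occupancy."""

import math

import numpy as np
import pandas as pd
import pytest

from spindlemc import (
    ModelParams,
    RidgePattern,
    alignment_rmsd,
    expected_orientation,
    inner_ring_mean_ar,
    mean_speed_timeseries,
    on_off_ridge_ratio,
    radial_profile,
    velocity_radial_histogram,
)
from spindlemc.analysis import _disc_area_in_box

L = 1200.0
CENTER = np.array([600.0, 600.0])


def _frame(x, y, phi=None, a=42.0, b=10.5, ids=None, mcs=0):
    n = len(x)
    return pd.DataFrame({
        "mcs": np.full(n, mcs), "id": ids if ids is not None else np.arange(n),
        "parent_id": -1, "x": x, "y": y,
        "a": np.broadcast_to(a, n).astype(float),
        "b": np.broadcast_to(b, n).astype(float),
        "phi": phi if phi is not None else np.zeros(n),
        "px": 0.0, "py": 0.0,
    })


def _ring_frame(radius, n=64, phi_offset=0.0, **kw):
    az = 2 * np.pi * np.arange(n) / n
    return _frame(CENTER[0] + radius * np.cos(az),
                  CENTER[1] + radius * np.sin(az),
                  phi=(az + phi_offset) % (2 * np.pi), **kw), az


# --------------------------------------------------------------------------
# expected orientation
# --------------------------------------------------------------------------

@pytest.mark.parametrize("az_deg, defect, expected", [
    (30.0, 1, 120.0),    # +1: azimuth + 90 (mod 180)
    (120.0, 1, 30.0),    # modulo reduction: 210 -> 30
    (30.0, -1, 150.0),   # −1 first quadrant: 180 − azimuth
    (110.0, -1, 70.0),   # −1 second quadrant: 180 − azimuth
    (210.0, -1, 150.0),  # −1 third quadrant: 360 − azimuth (mod 180)
    (300.0, -1, 60.0),   # −1 fourth quadrant
])
def test_expected_orientation_quadrant_rules(az_deg, defect, expected):
    pos = CENTER + 100.0 * np.array([math.cos(math.radians(az_deg)),
                                     math.sin(math.radians(az_deg))])
    assert expected_orientation(pos, defect, CENTER, L) == pytest.approx(expected)


def test_expected_orientation_rejects_center():
    with pytest.raises(ValueError):
        expected_orientation(CENTER, 1, CENTER, L)
    with pytest.raises(ValueError):
        expected_orientation(CENTER, 2, CENTER + [1.0, 0.0], L)


# --------------------------------------------------------------------------
# alignment RMSD
# --------------------------------------------------------------------------

def test_rmsd_zero_for_perfect_tangential_alignment():
    frame, _ = _ring_frame(90.0, phi_offset=np.pi / 2)  # tangent = az + 90°
    stats = alignment_rmsd(frame, 1, CENTER, L)
    assert stats.rmsd == pytest.approx(0.0, abs=1e-9)
    assert stats.n_cells == 64


def test_rmsd_maximal_for_radial_cells():
    frame, _ = _ring_frame(90.0, phi_offset=0.0)  # radial = off by 90°
    stats = alignment_rmsd(frame, 1, CENTER, L)
    assert stats.rmsd == pytest.approx(90.0, abs=1e-9)


def test_rmsd_uniform_orientations_closed_form():
    """Random orientations: RMSD → 90/sqrt(3) ≈ 51.96°."""
    rng = np.random.default_rng(0)
    n = 40_000
    pos_az = rng.uniform(0, 2 * np.pi, n)
    frame = _frame(CENTER[0] + 200 * np.cos(pos_az),
                   CENTER[1] + 200 * np.sin(pos_az),
                   phi=rng.uniform(0, np.pi, n))
    stats = alignment_rmsd(frame, 1, CENTER, L)
    expected = 90.0 / math.sqrt(3.0)
    # SE of the RMSD estimate at this n is ~0.2°
    assert stats.rmsd == pytest.approx(expected, abs=1.0)
    # un-rooted variant returns the mean square
    msd = alignment_rmsd(frame, 1, CENTER, L, root=False).rmsd
    assert msd == pytest.approx(stats.rmsd ** 2, rel=1e-12)


def test_rmsd_invariant_under_global_rotation():
    rng = np.random.default_rng(1)
    n = 300
    pos = CENTER + rng.uniform(-250, 250, (n, 2))
    phi = rng.uniform(0, np.pi, n)
    frame = _frame(pos[:, 0], pos[:, 1], phi=phi)
    base = alignment_rmsd(frame, 1, CENTER, L).rmsd
    theta = 0.73
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    pos2 = CENTER + (pos - CENTER) @ rot.T
    frame2 = _frame(pos2[:, 0], pos2[:, 1], phi=(phi + theta) % (2 * np.pi))
    assert alignment_rmsd(frame2, 1, CENTER, L).rmsd == pytest.approx(
        base, rel=1e-9)


def test_rmsd_requires_cells():
    with pytest.raises(ValueError):
        alignment_rmsd(_frame(np.array([]), np.array([])), 1, CENTER, L)


# --------------------------------------------------------------------------
# radial profiles
# --------------------------------------------------------------------------

def test_disc_area_in_box_regimes():
    assert _disc_area_in_box(100.0, L) == pytest.approx(math.pi * 1e4)
    assert _disc_area_in_box(L, L) == pytest.approx(L * L)
    # between L/2 and L/sqrt(2): partial clipping, monotone
    r1, r2 = 0.55 * L, 0.65 * L
    a1, a2 = _disc_area_in_box(r1, L), _disc_area_in_box(r2, L)
    assert math.pi * (L / 2) ** 2 < a1 < a2 < L * L


def test_density_profile_uniform_is_flat():
    rng = np.random.default_rng(5)
    n = 20_000
    frame = _frame(rng.uniform(0, L, n), rng.uniform(0, L, n))
    prof = radial_profile(frame, CENTER, L, quantity="density")
    # counting noise per ring is small at this n
    assert np.all(np.abs(prof.value) < 0.12)


def test_density_profile_concentrated_in_first_ring():
    rng = np.random.default_rng(6)
    n = 500
    r = rng.uniform(0, 55, n)
    az = rng.uniform(0, 2 * np.pi, n)
    frame = _frame(CENTER[0] + r * np.cos(az), CENTER[1] + r * np.sin(az))
    prof = radial_profile(frame, CENTER, L, quantity="density")
    assert prof.value[0] > 50.0        # enormous excess
    assert np.allclose(prof.value[1:], -1.0)   # −100% elsewhere
    assert prof.count[0] == n


def test_ring_counts_match_numpy_histogram_oracle():
    rng = np.random.default_rng(7)
    n = 1000
    frame = _frame(rng.uniform(0, L, n), rng.uniform(0, L, n))
    prof = radial_profile(frame, CENTER, L, quantity="density")
    d = np.column_stack([frame.x - CENTER[0], frame.y - CENTER[1]])
    d -= L * np.floor(d / L + 0.5)
    r = np.hypot(d[:, 0], d[:, 1])
    expected, _ = np.histogram(r, bins=prof.edges)
    assert np.array_equal(prof.count, expected)


def test_area_weighted_density_deviation_conserves():
    """With within-range normalization and all cells inside the range,
    the area-weighted mean deviation is zero."""
    rng = np.random.default_rng(8)
    n = 3000
    r = 590.0 * np.sqrt(rng.uniform(0, 1, n))
    az = rng.uniform(0, 2 * np.pi, n)
    frame = _frame(CENTER[0] + r * np.cos(az), CENTER[1] + r * np.sin(az))
    prof = radial_profile(frame, CENTER, L, quantity="density",
                          normalization="within_range")
    weighted = np.nansum(prof.value * prof.area) / prof.area.sum()
    assert weighted == pytest.approx(0.0, abs=1e-9)


def test_ar_profile_and_empty_ring_flag():
    frame, _ = _ring_frame(90.0)      # all cells in ring 2 (60–120)
    frame["a"] = 21.0
    frame["b"] = 10.5
    prof = radial_profile(frame, CENTER, L, quantity="aspect_ratio")
    assert prof.value[1] == pytest.approx(2.0)
    assert np.isnan(prof.value[0]) and np.isnan(prof.value[5])


# --------------------------------------------------------------------------
# velocity histogram
# --------------------------------------------------------------------------

def _two_frames(p0, p1, dt_mcs=4000):
    f0 = _frame(p0[:, 0], p0[:, 1], mcs=0)
    f1 = _frame(p1[:, 0], p1[:, 1], mcs=dt_mcs)
    return pd.concat([f0, f1], ignore_index=True)


def test_velocity_histogram_radial_motion_peaks_at_zero():
    n = 100
    az = 2 * np.pi * np.arange(n) / n
    p0 = CENTER + 150.0 * np.column_stack([np.cos(az), np.sin(az)])
    p1 = CENTER + 160.0 * np.column_stack([np.cos(az), np.sin(az)])
    edges, counts = velocity_radial_histogram(_two_frames(p0, p1), CENTER, L)
    assert counts[0] == n and counts[1:].sum() == 0


def test_velocity_histogram_chirality_convention():
    """Counterclockwise circular motion lands in the 270° bin (90° is
    clockwise by this package's convention)."""
    n = 100
    az = 2 * np.pi * np.arange(n) / n
    p0 = CENTER + 150.0 * np.column_stack([np.cos(az), np.sin(az)])
    daz = 0.05
    p1 = CENTER + 150.0 * np.column_stack([np.cos(az + daz), np.sin(az + daz)])
    edges, counts = velocity_radial_histogram(_two_frames(p0, p1), CENTER, L)
    k270 = int(np.searchsorted(edges, 270.0, side="right")) - 1
    assert counts[k270] == n
    # clockwise → 90°
    p1cw = CENTER + 150.0 * np.column_stack([np.cos(az - daz), np.sin(az - daz)])
    _, counts_cw = velocity_radial_histogram(_two_frames(p0, p1cw), CENTER, L)
    k90 = int(np.searchsorted(edges, 90.0, side="right")) - 1
    assert counts_cw[k90] == n


def test_velocity_histogram_isotropic_walk_is_flat():
    rng = np.random.default_rng(9)
    n = 30_000
    p0 = CENTER + rng.uniform(-300, 300, (n, 2))
    p1 = p0 + rng.normal(0, 3.0, (n, 2))
    edges, counts = velocity_radial_histogram(_two_frames(p0, p1), CENTER, L)
    expected = n / len(counts)
    assert np.all(np.abs(counts - expected) < 5 * math.sqrt(expected))


def test_velocity_histogram_window_validation():
    p0 = CENTER + np.array([[100.0, 0.0]])
    traj = _two_frames(p0, p0 + 1.0, dt_mcs=100)   # only 1.5 min apart
    with pytest.raises(ValueError):
        velocity_radial_histogram(traj, CENTER, L, window_min=60.0)


# --------------------------------------------------------------------------
# ridge occupancy
# --------------------------------------------------------------------------

@pytest.fixture()
def pattern(default_params):
    return RidgePattern.from_params(default_params)


def test_ratio_zero_when_nobody_on_ridges(pattern):
    frame = _frame(CENTER[0] + np.array([30.0, -20.0]),
                   CENTER[1] + np.array([0.0, 10.0]))
    assert on_off_ridge_ratio(frame, pattern) == 0.0


def test_ratio_uniform_cells_is_about_one(pattern):
    rng = np.random.default_rng(10)
    n = 200_000
    frame = _frame(rng.uniform(0, L, n), rng.uniform(0, L, n))
    ratio = on_off_ridge_ratio(frame, pattern)
    # on-ridge area fraction ~1.4%: expected count ~2800, CV ~2%
    assert ratio == pytest.approx(1.0, abs=0.1)


def test_ratio_diverges_when_everyone_on_ridges(pattern):
    frame, _ = _ring_frame(60.0)
    assert on_off_ridge_ratio(frame, pattern) == math.inf


# --------------------------------------------------------------------------
# speeds
# --------------------------------------------------------------------------

def test_speeds_zero_for_frozen_cells():
    p0 = CENTER + np.array([[10.0, 0.0], [50.0, 5.0]])
    traj = _two_frames(p0, p0, dt_mcs=2000)
    out = mean_speed_timeseries(traj, L=L)
    assert np.allclose(out.speed_um_per_h, 0.0)


def test_speed_unit_conversion_1um_per_100mcs_is_40um_per_h():
    p0 = CENTER + np.array([[0.0, 0.0]])
    frames = []
    for k in range(3):
        frames.append(_frame(np.array([p0[0, 0] + k * 1.0]),
                             np.array([p0[0, 1]]), mcs=k * 100))
    out = mean_speed_timeseries(pd.concat(frames, ignore_index=True), L=L)
    assert np.allclose(out.speed_um_per_h, 40.0)
    assert np.allclose(out.sd_um_per_h, 0.0)
    assert (out.speed_um_per_h >= 0).all()


def test_speeds_need_two_frames():
    with pytest.raises(ValueError):
        mean_speed_timeseries(_frame(np.array([1.0]), np.array([2.0])), L=L)


# --------------------------------------------------------------------------
# inner-ring aspect ratio
# --------------------------------------------------------------------------

def test_inner_ring_mean_ar_and_empty_flag(pattern):
    inner = _frame(CENTER[0] + np.array([10.0, -30.0]),
                   CENTER[1] + np.array([5.0, 20.0]), a=42.0, b=10.5)
    assert inner_ring_mean_ar(inner, pattern) == pytest.approx(4.0)
    outer = _frame(CENTER[0] + np.array([100.0]), CENTER[1] + np.array([0.0]))
    assert math.isnan(inner_ring_mean_ar(outer, pattern))


def test_inner_ring_mean_ar_bruteforce_filter(pattern):
    rng = np.random.default_rng(11)
    n = 500
    x = rng.uniform(0, L, n)
    y = rng.uniform(0, L, n)
    a = rng.uniform(15, 45, n)
    b = a / rng.uniform(1, 5, n)
    frame = _frame(x, y)
    frame["a"], frame["b"] = a, b
    got = inner_ring_mean_ar(frame, pattern)
    d = np.column_stack([x, y]) - pattern.center
    d -= L * np.floor(d / L + 0.5)
    sel = np.hypot(d[:, 0], d[:, 1]) < 60.0
    assert got == pytest.approx(np.mean(a[sel] / b[sel]), rel=1e-12)
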