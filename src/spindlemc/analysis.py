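"""Quantification of snapshots and trajectories.

All functions are pure: they accept snapshot DataFrames (columns
``x, y, a, b, phi`` and, for trajectories, ``mcs`` and ``id``), lists
of :class:`~spindlemc.model_core.Cell`, or a live
:class:`~spindlemc.model_core.SimState`, and return plain results.
Angles cross this boundary in degrees; distances to a defect center
always use the minimum image, so the −1 defect at the box corner
``(0,0)`` is handled by the same code path as the +1 pattern center.

Implemented quantities:

* expected ridge-imposed orientation at a point and the RMSD of cell
  long axes from it (wrapped to [−90°, 90°));
* ring-binned radial profiles of normalized density deviation
  ``(rho_ring − rho_avg)/rho_avg`` or of mean aspect ratio;
* radial histograms of displacement directions over a time window
  (90°/270° = azimuthal motion; 90° is clockwise here);
* the on/off-ridge number-density ratio;
* mean cell speeds between stored frames;
* the mean aspect ratio inside the innermost ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model_core import Cell, RidgePattern, SimState, minimum_image, ridge_membership

__all__ = [
    "RadialProfile",
    "AlignmentStats",
    "expected_orientation",
    "alignment_rmsd",
    "radial_profile",
    "velocity_radial_histogram",
    "on_off_ridge_ratio",
    "mean_speed_timeseries",
    "inner_ring_mean_ar",
]

MINUTES_PER_MCS = 1.5 / 100.0


def _as_arrays(cells) -> pd.DataFrame:
    """Normalize any supported cell collection to a DataFrame."""
    if isinstance(cells, pd.DataFrame):
        return cells
    if isinstance(cells, SimState):
        return cells.to_frame()
    rows = {"x": [], "y": [], "a": [], "b": [], "phi": []}
    for c in cells:
        rows["x"].append(c.center[0])
        rows["y"].append(c.center[1])
        rows["a"].append(c.a)
        rows["b"].append(c.b)
        rows["phi"].append(c.phi)
    return pd.DataFrame(rows)


@dataclass
class RadialProfile:
    """Ring-binned statistic around a defect center."""

    edges: np.ndarray        # bin edges, μm
    value: np.ndarray        # per-ring statistic (NaN where ring is empty)
    count: np.ndarray        # cells per ring
    area: np.ndarray         # ring area within the periodic box, μm²
    quantity: str
    normalization: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_inner": self.edges[:-1], "r_outer": self.edges[1:],
            "value": self.value, "count": self.count, "area": self.area,
        })


@dataclass
class AlignmentStats:
    """Angular deviations from the ridge-imposed orientation."""

    deviations: np.ndarray   # wrapped to [−90°, 90°), degrees
    rmsd: float              # degrees (or mean square if root=False)
    n_cells: int


def expected_orientation(position, defect: int, center, L: float):
    """Ridge-imposed orientation (degrees in [0°, 180°)) at a position.

    For a +1 defect the alignment axis is the azimuth plus 90° (modulo
    180°): cells follow the circular ridges. For the −1 defect imposed
    by the periodic tiling, it is 180° minus the azimuth in the first
    and second quadrants and 360° minus the azimuth in the third and
    fourth — i.e. the mirror field of a saddle. Positions exactly at
    the center are rejected.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    d = minimum_image(pos - np.asarray(center, dtype=float), L)
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0.0):
        raise ValueError("expected orientation is undefined at the defect center")
    az = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    if defect == 1:
        theta = (az + 90.0) % 180.0
    elif defect == -1:
        theta = np.where(az < 180.0, 180.0 - az, 360.0 - az) % 180.0
    else:
        raise ValueError(f"defect charge must be +1 or -1, got {defect}")
    out = theta % 180.0
    if np.ndim(position) == 1:
        return float(out[0])
    return out


def alignment_rmsd(cells, defect: int, center, L: float,
                   root: bool = True) -> AlignmentStats:
    """RMSD of cell long-axis orientations from the expected alignment.

    Deviations are wrapped to [−90°, 90°) (orientations are nematic).
    ``root=False`` returns the mean squared deviation instead of its
    root, for comparison with un-rooted conventions.
    """
    df = _as_arrays(cells)
    if len(df) == 0:
        raise ValueError("alignment_rmsd needs at least one cell")
    pos = df[["x", "y"]].to_numpy(float)
    d = minimum_image(pos - np.asarray(center, float), L)
    keep = np.hypot(d[:, 0], d[:, 1]) > 0.0
    pos = pos[keep]
    theta = np.degrees(df["phi"].to_numpy(float)[keep]) % 180.0
    theta_e = expected_orientation(pos, defect, center, L)
    dev = (theta - theta_e + 90.0) % 180.0 - 90.0
    msd = float(np.mean(dev ** 2))
    return AlignmentStats(
        deviations=dev,
        rmsd=math.sqrt(msd) if root else msd,
        n_cells=int(keep.sum()),
    )


from .model_core import disc_area_in_box as _disc_area_in_box


def radial_profile(cells, center, L: float, quantity: str = "density",
                   bin_width: float = 60.0, r_max: float = 600.0,
                   normalization: str = "whole_box",
                   box_area: Optional[float] = None) -> RadialProfile:
    """Ring statistics versus minimum-image distance from a center.

    ``density`` mode returns the normalized density deviation
    ``(rho_ring − rho_avg)/rho_avg`` per ring, with ``rho_avg`` the
    whole-box average (default) or the average within ``r_max``
    (``normalization="within_range"``). ``aspect_ratio`` mode returns
    the per-ring mean AR. Rings with no cells hold NaN, never zero.
    Ring areas account exactly for the clipping of large rings by the
    periodic box.
    """
    df = _as_arrays(cells)
    pos = df[["x", "y"]].to_numpy(float)
    d = minimum_image(pos - np.asarray(center, float), L)
    r = np.hypot(d[:, 0], d[:, 1])
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    areas = np.array([
        _disc_area_in_box(edges[i + 1], L) - _disc_area_in_box(edges[i], L)
        for i in range(len(edges) - 1)
    ])
    counts, _ = np.histogram(r, bins=edges)
    if quantity == "aspect_ratio":
        ar = (df["a"] / df["b"]).to_numpy(float)
        idx = np.digitize(r, edges) - 1
        value = np.full(len(edges) - 1, np.nan)
        for k in range(len(edges) - 1):
            sel = idx == k
            if sel.any():
                value[k] = float(np.mean(ar[sel]))
        return RadialProfile(edges, value, counts, areas, quantity)
    if quantity != "density":
        raise ValueError(f"unknown quantity {quantity!r}")
    if normalization == "whole_box":
        area_ref = box_area if box_area is not None else L * L
        rho_avg = len(df) / area_ref
    elif normalization == "within_range":
        inside = r <= r_max
        rho_avg = inside.sum() / _disc_area_in_box(min(r_max, L / math.sqrt(2.0)), L)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_ring = np.where(areas > 0, counts / np.where(areas > 0, areas, 1.0), np.nan)
        value = (rho_ring - rho_avg) / rho_avg
    value[areas <= 0] = np.nan
    return RadialProfile(edges, value, counts, areas, quantity, normalization)


def velocity_radial_histogram(trajectory: pd.DataFrame, center, L: float,
                              window_min: float = 60.0,
                              start_mcs: Optional[int] = None,
                              bin_width_deg: float = 30.0,
                              ) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of displacement direction relative to the outward radial.

    Takes the stored frame at ``start_mcs`` (default: first frame) and
    the first frame at least ``window_min`` minutes later; cells present
    in both (matched by id) contribute the angle between their
    minimum-image displacement and the outward radial direction at the
    window start. Angles in [0°, 360°); by this package's chirality
    convention 90° is clockwise and 270° counterclockwise azimuthal
    motion (both perpendicular to the radial direction). Bins are
    *centered* on 0°, ``bin_width_deg``, ... so purely radial or purely
    azimuthal motion falls squarely inside a bin rather than on a seam.

    Returns ``(bin_edges_deg, counts)``; the first edge is negative
    (the 0°-centered bin).
    """
    mcs_values = np.sort(trajectory["mcs"].unique())
    if start_mcs is None:
        start_mcs = int(mcs_values[0])
    window_mcs = window_min / MINUTES_PER_MCS
    later = mcs_values[mcs_values >= start_mcs + window_mcs - 1e-9]
    if len(later) == 0 or start_mcs not in mcs_values:
        raise ValueError("trajectory does not span the requested window")
    f0 = trajectory[trajectory["mcs"] == start_mcs].set_index("id")
    f1 = trajectory[trajectory["mcs"] == later[0]].set_index("id")
    common = f0.index.intersection(f1.index)
    if len(common) == 0:
        raise ValueError("no cells persist across the window")
    p0 = f0.loc[common, ["x", "y"]].to_numpy(float)
    p1 = f1.loc[common, ["x", "y"]].to_numpy(float)
    disp = minimum_image(p1 - p0, L)
    radial = minimum_image(p0 - np.asarray(center, float), L)
    rn = np.hypot(radial[:, 0], radial[:, 1])
    ok = (rn > 0) & (np.hypot(disp[:, 0], disp[:, 1]) > 0)
    rhat = radial[ok] / rn[ok, None]
    d = disp[ok]
    dot = rhat[:, 0] * d[:, 0] + rhat[:, 1] * d[:, 1]
    cross = rhat[:, 0] * d[:, 1] - rhat[:, 1] * d[:, 0]
    ang = np.degrees(np.arctan2(-cross, dot)) % 360.0
    # fold into bins centered on multiples of the bin width
    folded = (ang + 0.5 * bin_width_deg) % 360.0
    inner = np.arange(0.0, 360.0 + 0.5 * bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(folded, bins=inner)
    return inner - 0.5 * bin_width_deg, counts


def on_off_ridge_ratio(cells, pattern: RidgePattern) -> float:
    """Ratio of on-ridge to off-ridge cell number densities.

    A cell counts as on-ridge iff its *center* lies on a ridge annulus.
    Areas are computed analytically from the annuli. Returns ``inf``
    when every cell sits on a ridge (degenerate fixture).
    """
    df = _as_arrays(cells)
    if len(df) == 0:
        raise ValueError("on_off_ridge_ratio needs at least one cell")
    pts = df[["x", "y"]].to_numpy(float)
    on = ridge_membership(pts, pattern)
    n_on = int(np.count_nonzero(on))
    n_off = len(df) - n_on
    area_on = pattern.ridge_area()
    area_off = pattern.L ** 2 - area_on
    if n_off == 0:
        return math.inf
    return (n_on / area_on) / (n_off / area_off)


def mean_speed_timeseries(trajectory: pd.DataFrame,
                          L: Optional[float] = None) -> pd.DataFrame:
    """Mean cell speed between consecutive stored frames.

    Speeds are per-cell displacement magnitudes (minimum image when
    ``L`` is given) divided by the frame interval, averaged over the
    cells present in both frames; the quoted dispersion is the SD over
    cells. Times are converted at 1.5 min per 100 MCS. Returns columns
    ``time_h, speed_um_per_h, sd_um_per_h, n_cells``.
    """
    mcs_values = np.sort(trajectory["mcs"].unique())
    if len(mcs_values) < 2:
        raise ValueError("need at least two stored frames to compute speeds")
    rows = []
    for m0, m1 in zip(mcs_values[:-1], mcs_values[1:]):
        f0 = trajectory[trajectory["mcs"] == m0].set_index("id")
        f1 = trajectory[trajectory["mcs"] == m1].set_index("id")
        common = f0.index.intersection(f1.index)
        d = (f1.loc[common, ["x", "y"]].to_numpy(float)
             - f0.loc[common, ["x", "y"]].to_numpy(float))
        if L is not None:
            d = minimum_image(d, L)
        dist = np.hypot(d[:, 0], d[:, 1])
        dt_h = (m1 - m0) * MINUTES_PER_MCS / 60.0
        rows.append({
            "time_h": m1 * MINUTES_PER_MCS / 60.0,
            "speed_um_per_h": float(np.mean(dist)) / dt_h,
            "sd_um_per_h": float(np.std(dist)) / dt_h,
            "n_cells": len(common),
        })
    return pd.DataFrame(rows)


def inner_ring_mean_ar(cells, pattern: RidgePattern) -> float:
    """Mean aspect ratio of cells inside the innermost ring region.

    The inner region is the open disc of radius equal to the first ring
    radius around the pattern (+1) center, under the minimum image.
    Returns NaN when no cell is inside (a realistic outcome in
    motility-free runs).
    """
    if not pattern.radii:
        raise ValueError("pattern has no rings")
    df = _as_arrays(cells)
    pos = df[["x", "y"]].to_numpy(float)
    d = minimum_image(pos - pattern.center, pattern.L)
    r = np.hypot(d[:, 0], d[:, 1])
    sel = r < pattern.radii[0]
    if not sel.any():
        return float("nan")
    ar = (df["a"] / df["b"]).to_numpy(float)
    return float(np.mean(ar[sel]))
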