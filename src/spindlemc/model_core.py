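"""Domain types, periodic geometry, and single-cell energies.

Cells are deformable ellipses on a doubly periodic square substrate of
side ``L``. A concentric pattern of narrow elevated ridge rings imposes a
+1 nematic defect at the pattern center; the periodic tiling of that
pattern automatically produces a −1 defect at the box corners, so no
separate −1 geometry is ever constructed.

Each cell carries a position, semi-axis radii ``a >= b > 0``, an
orientation angle ``phi`` of the major axis, and a polarity vector used
by the motility energy. Single-cell energies implemented here:

* shape energy — quartic penalty on relative deviations of area
  ``A = pi*a*b`` from ``A_pref`` and of aspect ratio ``AR = a/b`` from
  ``AR_pref``: ``E_X = k_X (d^2 - d^3/3 + 4 d^4)`` for each relative
  deviation ``d``;
* core energy — ``k_core (1/a^4 + 1/b^4)``, a steep barrier preventing
  cells from being squeezed to nothing;
* ridge energy — ``k_r * Y`` where the overlap fraction ``Y`` is
  estimated from 192 "feeler" points on three concentric similar
  ellipses (full size, 2/3, and 1/3 scale; 64 points each, evenly
  spaced in the parametric polar angle).

Everything here is a pure, numpy-level reference implementation; the
compiled Monte Carlo engine in :mod:`spindlemc._kernels` re-implements
the same formulas and is validated against these functions in the test
suite.

Units: lengths in μm, angles in radians internally (degrees only at I/O
boundaries), energies in units of the Metropolis temperature ``T = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Cell",
    "ModelParams",
    "RidgePattern",
    "SimState",
    "minimum_image",
    "shape_energy",
    "core_energy",
    "ridge_membership",
    "feeler_points",
    "ridge_overlap_fraction",
    "ridge_energy",
]


# --------------------------------------------------------------------------
# periodic geometry
# --------------------------------------------------------------------------

def disc_area_in_box(r: float, L: float) -> float:
    """Area of {q : |minimum_image(q - c)| <= r} in a periodic LxL box.

    A full disc for ``r <= L/2``; clipped by the fundamental square for
    larger radii; the whole box beyond ``L/sqrt(2)``.
    """
    if r <= 0.0:
        return 0.0
    if r <= L / 2.0:
        return float(np.pi) * r * r
    if r >= L / np.sqrt(2.0):
        return L * L
    h = L / 2.0
    seg = r * r * np.arccos(h / r) - h * np.sqrt(r * r - h * h)
    return float(np.pi * r * r - 4.0 * seg)


def minimum_image(displacement, L: float):
    """Wrap a displacement into the primary image ``[-L/2, L/2)``.

    Works on a single 2-vector or any array whose last axis is the
    component axis. Idempotent; adding any lattice vector of the box to
    the input leaves the result unchanged.
    """
    if L <= 0:
        raise ValueError(f"box side L must be positive, got {L}")
    d = np.asarray(displacement, dtype=float)
    return d - L * np.floor(d / L + 0.5)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Cell:
    """One elliptical cell.

    ``a`` and ``b`` are the semi-major and semi-minor axis *radii* (μm),
    with the convention ``a >= b > 0`` maintained by the dynamics (moves
    that would violate it are rejected outright). ``phi`` is the angle
    of the major axis with the x-axis; the orientation is physically
    nematic (defined modulo π) but stored as given. ``polarity`` is the
    motility direction; only its sign along the major axis enters the
    motility energy, while its magnitude carries the displacement
    -feedback memory.
    """

    id: int
    center: np.ndarray
    a: float
    b: float
    phi: float
    polarity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    parent_id: Optional[int] = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.polarity = np.asarray(self.polarity, dtype=float)
        if not (self.a >= self.b > 0):
            raise ValueError(
                f"cell axes must satisfy a >= b > 0, got a={self.a}, b={self.b}"
            )

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)

    @property
    def aspect_ratio(self) -> float:
        return float(self.a / self.b)

    @property
    def u(self) -> np.ndarray:
        """Unit vector along the major axis."""
        return np.array([np.cos(self.phi), np.sin(self.phi)])


#: Table of model defaults. Lengths μm, energies in units of T, times in MCS
#: unless noted. 100 MCS corresponds to 1.5 min of experimental time.
@dataclass
class ModelParams:
    # Metropolis temperature (sets the energy scale; not physical).
    T: float = 1.0
    # maximum proposal amplitudes
    delta_r: float = 1.2            # μm, displacement
    delta_phi: float = np.deg2rad(2.0)  # rad, rotation
    delta_a: float = 0.6            # μm, semi-major change
    delta_b: float = 0.6            # μm, semi-minor change
    # preferred geometry and stiffnesses
    A_pref: float = 1400.0          # μm^2
    AR_pref: float = 4.0
    k_A: float = 18.0
    k_AR: float = 4.0
    k_core: float = 1600.0          # T μm^4
    # cell–cell interaction
    eps0: float = 0.5
    mu: float = 1.0
    nu: float = 1.0
    rc_maj: float = 100.0           # μm, cutoff ellipse semi-major
    rc_min: float = 43.75           # μm, cutoff ellipse semi-minor
    skin: float = 25.0              # μm, neighbor-list rebuild threshold
    # motility and polarity
    k_move: float = 1.0             # T/μm
    tau_pol: float = 2000.0         # MCS (30 min at 1.5 min / 100 MCS)
    tau_flip_prob: float = 0.01     # reversal probability per check
    flip_period: int = 100          # MCS between reversal checks
    polarity_feedback: str = "accepted"   # or "proposed"
    # ridge pattern
    k_r: float = 120.0
    ring_spacing: float = 60.0      # μm
    ridge_width: float = 4.0        # μm (not stated for simulations; see docs)
    n_feeler_rings: int = 3
    n_feeler_points: int = 64
    # box and schedule
    L: float = 1200.0               # μm
    mcs_to_min: float = 1.5 / 100.0  # minutes of real time per MCS
    move_mix: Tuple[float, float, float, float] = (0.10, 0.20, 0.35, 0.35)
    rho_init: float = 100.0 / 1.44   # cells/mm^2 (100 cells in default box)
    rho_f: float = 3000.0 / 1.44     # cells/mm^2 (3000 cells in default box)
    n_init: Optional[int] = None     # overrides rho_init when set
    terminal_count: Optional[int] = None  # overrides rho_f when set
    r0: float = 10.0                # μm, initial circular-cell radius
    relax_time: float = 10.0        # h without division after seeding
    division_period: int = 100      # MCS between divisions in growth phase
    daughter_factor: float = 0.4
    alpha: float = 2.0              # division shape sensitivity
    division_mode: str = "shape_dependent"  # or "uniform_random"
    daughter_polarity: str = "inherit"      # or "random"

    # -- derived quantities ------------------------------------------------
    @property
    def box_area_mm2(self) -> float:
        return (self.L / 1000.0) ** 2

    @property
    def n_init_effective(self) -> int:
        if self.n_init is not None:
            return int(self.n_init)
        return int(round(self.rho_init * self.box_area_mm2))

    @property
    def terminal_count_effective(self) -> int:
        if self.terminal_count is not None:
            return int(self.terminal_count)
        return int(round(self.rho_f * self.box_area_mm2))

    @property
    def relax_mcs(self) -> int:
        """Relaxation time converted to MCS (10 h -> 40,000 MCS)."""
        return int(round(self.relax_time * 60.0 / self.mcs_to_min))

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def validate(self) -> "ModelParams":
        pos = [
            "T", "delta_r", "delta_phi", "delta_a", "delta_b", "A_pref",
            "AR_pref", "k_A", "k_AR", "k_core", "eps0", "rc_maj", "rc_min",
            "skin", "tau_pol", "ring_spacing", "ridge_width", "L", "r0",
            "mcs_to_min", "daughter_factor",
        ]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be positive, got {getattr(self, name)}")
        for name in ("k_move", "k_r", "alpha", "rho_init", "rho_f", "relax_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not 0.0 <= self.tau_flip_prob <= 1.0:
            raise ValueError("tau_flip_prob must lie in [0, 1]")
        if not 0.0 < self.daughter_factor < 1.0:
            raise ValueError("daughter_factor must lie in (0, 1)")
        if len(self.move_mix) != 4 or any(p < 0 for p in self.move_mix):
            raise ValueError("move_mix must be 4 non-negative probabilities")
        if abs(sum(self.move_mix) - 1.0) > 1e-9:
            raise ValueError(f"move_mix must sum to 1, got {sum(self.move_mix)}")
        if self.AR_pref < 1:
            raise ValueError("AR_pref must be >= 1")
        if self.rc_maj < self.rc_min:
            raise ValueError("rc_maj must be >= rc_min")
        if self.division_period <= 0 or self.flip_period <= 0:
            raise ValueError("division_period and flip_period must be positive")
        if self.division_mode not in ("shape_dependent", "uniform_random"):
            raise ValueError(f"unknown division_mode {self.division_mode!r}")
        if self.polarity_feedback not in ("accepted", "proposed"):
            raise ValueError(f"unknown polarity_feedback {self.polarity_feedback!r}")
        if self.daughter_polarity not in ("inherit", "random"):
            raise ValueError(f"unknown daughter_polarity {self.daughter_polarity!r}")
        return self

    @classmethod
    def field_names(cls) -> Tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass
class RidgePattern:
    """Concentric ridge annuli centered in a periodic box.

    Ring center-radii are ``k * ring_spacing`` for ``k = 1..K``; there
    is no ring at radius zero, so the "innermost ring" region is the
    open disc of radius ``ring_spacing``. Membership is evaluated with
    the minimum-image distance to the pattern center, i.e. the distance
    to the *nearest periodic image* — so each ring is automatically
    truncated to the Voronoi cell of its own center, exactly the
    tiling of concentric circle patterns that meets at the box
    boundary. Rings extend to the largest minimum-image distance
    ``L/sqrt(2)``: the rings beyond ``L/2`` appear as the hyperbolic
    arcs around the box corner that impose the −1 saddle there.
    """

    center: np.ndarray
    ring_spacing: float
    ring_width: float
    k_r: float
    L: float
    radii: Tuple[float, ...] = ()

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        r_max = self.L / np.sqrt(2.0)
        if not self.radii:
            n = int(np.ceil(r_max / self.ring_spacing))
            radii = [k * self.ring_spacing for k in range(1, n + 1)]
            self.radii = tuple(r for r in radii if r < r_max)
        if any(r >= r_max for r in self.radii):
            raise ValueError("ring radii must all be below L/sqrt(2)")

    @classmethod
    def from_params(cls, params: ModelParams) -> "RidgePattern":
        return cls(
            center=np.array([params.L / 2.0, params.L / 2.0]),
            ring_spacing=params.ring_spacing,
            ring_width=params.ridge_width,
            k_r=params.k_r,
            L=params.L,
        )

    @property
    def minus_one_center(self) -> np.ndarray:
        """Center of a −1 saddle of the periodic tiling.

        Topological charge on the torus is conserved: a tiling with a
        +1 ring pattern at the cell center necessarily carries another
        +1 at the Voronoi corner (the ridge arcs there close into
        loops, and the tangent of any closed loop winds by +360°) and
        compensating −1 saddles at the two *edge midpoints* of the
        tile. This returns the midpoint between the pattern center and
        its vertical periodic image; the horizontal one, related by
        symmetry, is ``minus_one_center_alt``.
        """
        return np.array([self.center[0] % self.L,
                         (self.center[1] + self.L / 2.0) % self.L])

    @property
    def minus_one_center_alt(self) -> np.ndarray:
        """The symmetry-equivalent second −1 saddle (horizontal)."""
        return np.array([(self.center[0] + self.L / 2.0) % self.L,
                         self.center[1] % self.L])

    def ridge_area(self) -> float:
        """Total ridge area, exact including the periodic clipping of
        rings beyond L/2 (the corner arcs)."""
        w = self.ring_width / 2.0
        return float(sum(
            disc_area_in_box(r + w, self.L) - disc_area_in_box(r - w, self.L)
            for r in self.radii))


@dataclass
class SimState:
    """Full mutable simulation state in structure-of-arrays layout.

    The arrays are preallocated to the terminal cell count; ``n`` cells
    are alive. ``rng`` is the explicit xoshiro256** state; identical
    seed and parameters give bit-identical trajectories. Neighbor lists
    are stored row-per-cell (``nbr[i, :nnbr[i]]``) and kept consistent
    with the padded interaction cutoff (see :mod:`spindlemc.interactions`).
    """

    params: ModelParams
    pattern: RidgePattern
    rng: np.ndarray
    x: np.ndarray
    y: np.ndarray
    a: np.ndarray
    b: np.ndarray
    phi: np.ndarray
    px: np.ndarray
    py: np.ndarray
    ids: np.ndarray
    parent: np.ndarray
    n: int = 0
    mcs: int = 0
    next_id: int = 0
    nbr: Optional[np.ndarray] = None
    nnbr: Optional[np.ndarray] = None
    # accumulated displacement since last full neighbor-list build (μm)
    moved: Optional[np.ndarray] = None
    # accumulated rotation metric (rc_maj·|Δφ|) since the cell's own
    # list row was last built (μm)
    rotm: Optional[np.ndarray] = None
    # cached per-cell ridge energies (kept current by the engine)
    ridge_cache: Optional[np.ndarray] = None
    # cached cos(phi)/sin(phi), maintained by every mutating code path
    cphi: Optional[np.ndarray] = None
    sphi: Optional[np.ndarray] = None

    @classmethod
    def allocate(cls, params: ModelParams, pattern: RidgePattern,
                 rng: np.ndarray, capacity: int) -> "SimState":
        f = lambda: np.zeros(capacity, dtype=float)
        return cls(
            params=params, pattern=pattern, rng=rng,
            x=f(), y=f(), a=f(), b=f(), phi=f(), px=f(), py=f(),
            ids=np.zeros(capacity, dtype=np.int64),
            parent=np.full(capacity, -1, dtype=np.int64),
            moved=f(),
            rotm=f(),
            ridge_cache=f(),
            cphi=f(),
            sphi=f(),
        )

    @property
    def capacity(self) -> int:
        return self.x.shape[0]

    def cell(self, i: int) -> Cell:
        return Cell(
            id=int(self.ids[i]),
            parent_id=None if self.parent[i] < 0 else int(self.parent[i]),
            center=np.array([self.x[i], self.y[i]]),
            a=float(self.a[i]), b=float(self.b[i]), phi=float(self.phi[i]),
            polarity=np.array([self.px[i], self.py[i]]),
        )

    def cells(self) -> list:
        return [self.cell(i) for i in range(self.n)]

    def to_frame(self):
        """Snapshot as a pandas DataFrame (one row per living cell)."""
        import pandas as pd

        n = self.n
        return pd.DataFrame({
            "mcs": np.full(n, self.mcs, dtype=np.int64),
            "id": self.ids[:n].copy(),
            "parent_id": self.parent[:n].copy(),
            "x": self.x[:n].copy(), "y": self.y[:n].copy(),
            "a": self.a[:n].copy(), "b": self.b[:n].copy(),
            "phi": self.phi[:n].copy(),
            "px": self.px[:n].copy(), "py": self.py[:n].copy(),
        })

    def density_mm2(self) -> float:
        return self.n / self.params.box_area_mm2


# --------------------------------------------------------------------------
# single-cell energies
# --------------------------------------------------------------------------

def _quartic_penalty(delta: float, k: float) -> float:
    # k * (d^2 - d^3/3 + 4 d^4): shallow near 0, steep for |d| >~ 1
    return k * (delta * delta - delta ** 3 / 3.0 + 4.0 * delta ** 4)


def shape_energy(cell: Cell, params: ModelParams) -> float:
    """Quartic penalty on relative area and aspect-ratio deviations.

    Zero exactly at ``(A_pref, AR_pref)`` and positive elsewhere.
    """
    dA = (cell.area - params.A_pref) / params.A_pref
    dAR = (cell.aspect_ratio - params.AR_pref) / params.AR_pref
    return _quartic_penalty(dA, params.k_A) + _quartic_penalty(dAR, params.k_AR)


def core_energy(cell: Cell, params: ModelParams) -> float:
    """Steep barrier ``k_core (1/a^4 + 1/b^4)`` against vanishing axes."""
    if cell.a <= 0 or cell.b <= 0:
        raise ValueError("cell axes must be positive")
    return params.k_core * (cell.a ** -4 + cell.b ** -4)


def ridge_membership(point, pattern: RidgePattern):
    """True where a point lies on a ridge annulus (minimum-image)."""
    p = np.asarray(point, dtype=float)
    d = minimum_image(p - pattern.center, pattern.L)
    r = np.hypot(d[..., 0], d[..., 1])
    half_w = pattern.ring_width / 2.0
    on = np.zeros(np.shape(r), dtype=bool)
    for radius in pattern.radii:
        on |= np.abs(r - radius) <= half_w
    if on.ndim == 0:
        return bool(on)
    return on


def feeler_points(cell: Cell, params: ModelParams) -> np.ndarray:
    """Sampling points used to estimate the cell–ridge overlap fraction.

    ``n_feeler_rings`` concentric similar ellipses at scales
    ``m / n_feeler_rings`` (m = n_rings..1), each carrying
    ``n_feeler_points`` points evenly spaced in the parametric polar
    angle. The cell center itself is not included.
    """
    scales = np.arange(params.n_feeler_rings, 0, -1) / params.n_feeler_rings
    theta = 2.0 * np.pi * np.arange(params.n_feeler_points) / params.n_feeler_points
    sx = np.outer(scales, np.cos(theta)).ravel()
    sy = np.outer(scales, np.sin(theta)).ravel()
    c, s = np.cos(cell.phi), np.sin(cell.phi)
    ex = cell.a * sx
    ey = cell.b * sy
    pts = np.empty((sx.size, 2))
    pts[:, 0] = cell.center[0] + ex * c - ey * s
    pts[:, 1] = cell.center[1] + ex * s + ey * c
    return pts


def ridge_overlap_fraction(cell: Cell, pattern: RidgePattern,
                           params: ModelParams) -> float:
    """Fraction Y = N_on / N_total of feeler points lying on ridges."""
    pts = feeler_points(cell, params)
    on = ridge_membership(pts, pattern)
    return float(np.count_nonzero(on)) / pts.shape[0]


def ridge_energy(cell: Cell, pattern: RidgePattern, params: ModelParams) -> float:
    """Cell–ridge overlap penalty ``k_r * Y``, in ``[0, k_r]``."""
    return pattern.k_r * ridge_overlap_fraction(cell, pattern, params)
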