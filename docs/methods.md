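# Model and methods

`spindlemc` simulates a proliferating monolayer of spindle-shaped cells
(3T6-fibroblast-like) on a flat, doubly periodic substrate carrying
narrow elevated ridges arranged in concentric rings. The ring pattern
imposes a +1 nematic defect at its center; the periodic tiling of the
pattern produces compensating −1 saddles between pattern images. The
package asks how
much of the cell-density structure that develops around such defects
can be explained by a shape-dependent division rule, with migration
otherwise unbiased.

## Cell representation

Each cell is a deformable ellipse: center `(x, y)` (μm), semi-axis
radii `a ≥ b > 0` (μm), orientation `φ` of the major axis (radians,
physically nematic), and a polarity vector `p` setting the preferred
direction of crawling. Area `A = πab` and aspect ratio `AR = a/b` are
always derived from the axes, never stored separately.

## Energies

All energies are expressed in units of the Metropolis temperature
`T = 1`, which is an effective fluctuation scale, not a physical
temperature.

**Shape.** Relative deviations `δ_A = (A − A_pref)/A_pref` and
`δ_AR = (AR − AR_pref)/AR_pref` are penalized by
`E_X = k_X (δ² − δ³/3 + 4δ⁴)`: nearly flat close to the preferred
value (cells trade area against height cheaply), steeply quartic for
large deviations. Defaults: `A_pref = 1400 μm²`, `AR_pref = 4`,
`k_A = 18`, `k_AR = 4`.

**Core.** `E_c = k_core (a⁻⁴ + b⁻⁴)` with `k_core = 1600 T μm⁴`
represents the incompressible nucleus: negligible at typical sizes
(≈ 0.13 at the preferred shape), divergent as an axis shrinks to zero.

**Cell–cell.** A modified Gay–Berne potential,
`U = 4ε (r⁻¹² − r⁻⁶)` at the scaled separation
`r = (|r₁₂| − σ + σ₀)/σ₀`, where the anisotropic contact scale is
`σ = (r̂ᵀ(γ₁+γ₂)⁻¹ r̂)^(−1/2)` with overlap matrices
`γᵢ = (lᵢ² − dᵢ²) ûᵢûᵢᵀ + dᵢ² I`, `lᵢ = √2 aᵢ`, `dᵢ = √2 bᵢ`, and
`σ₀ = √(2b₁² + 2b₂²)` the side-by-side contact scale. The well depth
is `ε = ε₀ ε_a^ν ε_b^μ` with `ε_a = [1 − χ²(û₁·û₂)²]^(−1/2)`
(head–tail symmetric; `χ` the usual shape-anisotropy factor) and
`ε_b = (σ₀/σ)²` in the dimensionless convention, so two circular cells
interact through a plain 12-6 potential of strength `ε₀ = 0.5` and
contact diameter `2b`. Parallel side-by-side contact is the deepest
configuration, which is what drives nematic order. The `√2` axis
convention and the dimensionless `ε_b` are chosen so that the circular
limit is exactly self-consistent (`σ = σ₀`); any constant rescaling of
`ε_b` is absorbed into `ε₀`.

The interaction is truncated by a *one-sided elliptical cutoff*: cell
`i` interacts with cells whose centers fall inside an ellipse of
semi-axes `(100, 43.75) μm` centered on `i` and oriented along `û_i`.
The pair function itself is symmetric; the cutoff is not, so no global
symmetric Hamiltonian exists — the Metropolis dynamics below are
nevertheless well defined, because each move's `ΔE` is the change of
the *moving* cell's local energy. Transiently coincident centers are
kept finite by flooring the scaled separation at `10⁻³` (and clamping
the quadratic form in the compiled path); the resulting enormous
repulsion is then rejected almost surely.

**Cell–ridge.** `E_ridge = k_r Υ`, where the overlap fraction
`Υ ∈ [0, 1]` is the fraction of 192 "feeler" points lying on a ridge:
64 points evenly spaced in the parametric polar angle on each of three
concentric similar ellipses at scales 1, 2/3, 1/3 of the cell (the
cell center itself is not a feeler point). Default `k_r = 120`,
configurable; larger `k_r` suppresses ridge crossing.

**Motility.** For a proposed displacement `Δr`,
`ΔE_move = −k_move (Π·Δr)/|Π|` with `Π = (û·p)û`: motion along the
major axis in the direction of the polarity is rewarded at
`k_move = 1 T/μm`; only the *sign* of `û·p` matters, not `|p|`. The
term vanishes when `p ⊥ û`.

## Ridge pattern geometry

Rings have center-radii `k · 60 μm` (no ring at radius zero; the
"innermost ring" region is the open disc of radius 60 μm) and width
4 μm. The width is a package choice — narrow relative to the spacing,
matching the thin fabricated ridges — and is configurable. Ring
membership uses the minimum-image distance to the pattern center,
which truncates every ring to the Voronoi cell of its nearest periodic
image. Rings extend to the largest minimum-image distance `L/√2`;
stopping them at `L/2` would leave a ridge-free zone of radius
≈ 0.2 L around the box corner (we verified that this reverses the
density signal there).

**Where the −1 defect lives.** Topological charge on the periodic box
must total zero, and the geometry is rigid about how that happens: the
ridge arcs near the box *corner* close into rounded-diamond loops, and
the tangent of any simple closed loop turns by +360°, so the corner is
a *second +1-like core* — empirically it shows exactly the +1
phenomenology (closed confinement, isotropic cells, and under
shape-dependent division a density increase). The compensating −1
saddles sit at the two Voronoi *edge midpoints* of the tile (center
+1, corner +1, midpoints −1 each: total 0). Around a midpoint the
ridge branches of neighboring images meet in hyperbola-like kinked
arcs; cells there stay elongated and the region depletes — the −1
phenomenology. `RidgePattern.minus_one_center` therefore returns the
edge midpoint (the second, symmetry-equivalent saddle is
`minus_one_center_alt`). The saddle is smeared: very close to the
midpoint the ridge-imposed director is nearly uniform (the −1 winding
is carried by the kink lines), so the quadrant rule for the expected
−1 orientation applies only beyond roughly one ring spacing from the
midpoint, up to the saddle phase of this construction.

## Monte Carlo dynamics

One Monte Carlo step (MCS) proposes a single move for every cell in a
fresh random order. Move kinds and maximum amplitudes (defaults):
displacement (10%, `δr = 1.2 μm`, uniform magnitude × uniform angle),
rotation (20%, `Δφ = 2δφ(𝕏−½)`, `δφ = 2°`), semi-major resize (35%,
`δa(𝕏−½)`, `δa = 0.6 μm`), semi-minor resize (35%, `δb = 0.6 μm`).
Moves are accepted with probability `min(1, e^(−ΔE/T))`. Resize
proposals violating `a ≥ b > 0` are rejected outright; orientation
identity is preserved (axes are never relabeled). On an accepted
rotation the polarity co-rotates by the same angle. 100 MCS correspond
to 1.5 min of real time.

After the sweep, each cell's polarity is updated as
`p ← (1 − 1/τ_pol) p + Δr_realized` with `τ_pol = 2000 MCS` (30 min)
and `Δr_realized` the displacement actually performed this MCS — zero
if none was proposed or the proposal was rejected. The
proposed-displacement variant of this feedback is available via
`polarity_feedback="proposed"` for sensitivity checks. Every 100 MCS
each polarity independently reverses (`p → −p`) with probability 0.01,
giving a mean reversal period of 150 min; reversals prevent globally
rotating states.

Sequencing within one MCS is: moves (random order), polarity feedback,
then at 100-MCS boundaries reversals, then (growth phase) one
division. The model does not fix this order physically; it is fixed
here for reproducibility.

## Growth

Runs start from `ρ_init ≈ 69.4 cells/mm²` (100 cells in the default
1200 μm box) of circular cells with radius 10 μm at uniformly random
non-overlapping positions, random orientations and random unit
polarities. Cells relax for 10 h (40,000 MCS) without dividing, then
exactly one cell divides every 100 MCS until the terminal count
(3000 cells ≈ 2083 cells/mm² in the default box; the count, derived
from `ρ_f` and the box area, is what the scheduler compares against).
The dividing cell is chosen with probability

    p_i ∝ exp(A_i/A_pref − α · AR_i/AR_pref),

computed with a max-shifted exponent for numerical stability: larger
cells divide more, and for `α > 0` more isotropic cells divide more.
`α = 2` is the default; `α = 0` removes the shape sensitivity and
`division_mode="uniform_random"` bypasses the weights entirely as a
control. Daughters get the parent's orientation and polarity and
0.4× its axes, centered at ±0.4 a along the major axis — they touch at
the parent center, stay inside its footprint, preserve the aspect
ratio, and deliberately do not conserve area (they regrow quickly when
space permits).

## Random numbers and reproducibility

All randomness flows through one explicit xoshiro256** stream seeded
from a single integer. The draw order is fixed: Fisher–Yates
permutation (descending index), per cell one kind draw plus the kind's
parameter draws, and exactly one acceptance draw per energy-evaluated
proposal (consumed also when `ΔE ≤ 0`, so that the stream position
never depends on floating-point noise in a near-zero `ΔE`); then one
reversal draw per cell at flip boundaries; then the division draw.
Identical seed and parameters give bit-identical trajectories of the
compiled engine. A pure-Python reference engine implements the same
draw order over independently written numpy energies and reproduces
compiled trajectories draw-for-draw (floats agree to ~1e-9 over
hundreds of MCS; the residual is fused-multiply-add contraction in the
compiled code). Replicates use seed = base + index, so parameter arms
share initial conditions seed-for-seed.

## Neighbor lists

Candidate lists per cell are built against the cutoff ellipse padded
by 0.6 × the 25 μm skin; the exact cutoff is re-applied at every
energy evaluation. Rebuild policy: a full rebuild on every division or
when a cell's accumulated displacement exceeds 0.3 × skin; when a
cell's accumulated rotation metric (`rc_maj · |Δφ|`, the worst-case
swing of its cutoff boundary) exceeds 0.3 × skin, only that cell's own
row is rebuilt — the one-sided cutoff means a rotation of `i` enters
no other cell's list. With these triggers every pair within
cutoff − 0.3·skin is provably always listed, which is stricter than
the documented cutoff − skin contract; the rotation-aware metric is a
package choice (a displacement-only trigger cannot bound the error of
a rotating cutoff ellipse).

## Analysis conventions

* Angles cross the API in degrees; orientations are reported modulo
  180°.
* Expected alignment at azimuth `θ_az`: `θ_az + 90° (mod 180°)` for
  the +1 defect; `180° − θ_az` (first/second quadrants) or
  `360° − θ_az` (third/fourth) for the −1 defect. Under the
  minimum-image azimuth, the +1 rule coincides everywhere with the
  tangent of the nearest ridge point, so the "nearest-ridge
  orientation" variant of the expected angle is the same function
  here.
* Alignment RMSD is the square root of the mean squared deviation
  wrapped to [−90°, 90°); the un-rooted mean square is available via
  `root=False`.
* Radial profiles use 60 μm rings out to 600 μm by default; density is
  reported as `(ρ_ring − ρ_avg)/ρ_avg` with the whole-box average (or
  the within-range average on request). Ring areas account exactly for
  the periodic clipping of rings beyond `L/2`. Empty rings yield NaN,
  never zero.
* Velocity-direction histograms use per-cell displacements over a
  60 min window; 90°/270° are azimuthal, and by this package's
  chirality convention 90° is clockwise. Bins are centered on the
  cardinal angles.
* A cell is "on a ridge" iff its center is; on/off-ridge areas are
  computed analytically from the annuli.
* Speeds are per-cell frame-to-frame displacements divided by the
  frame interval (1.5 min per 100 MCS), averaged over cells.

## Problem sizes used in the shipped studies

The package's replication studies run a 600 μm box (25 seeded cells,
750 terminal, rings at 60…420 μm) with 12 fixed seeds per parameter
arm for the division-rule comparison (α = 0 vs 2 at `k_r = 120`) and
10 seeds for the ridge-strength comparison (`k_r = 60` vs 120, matched
at 800 cells/mm²). These retain the absolute ridge geometry, densities
and schedule of the full-size system while keeping a complete study on
a single core; claims tested at this scale are directional
(one-sided paired tests across shared seeds), not quantitative curve
reproductions.

At this scale the study robustly reproduces the packing and migration
phenomenology: alignment RMSD rises with density and falls with ridge
strength, the on/off-ridge occupancy ratio collapses as `k_r` goes
60 → 120, mean speeds fall as the monolayer packs, and motion around
the +1 defect is azimuthal with no clear net radial flow. The
*division-rule contrasts at the defect cores* (more density at the +1
core and less at the −1 saddles for α = 2 vs 0; lower core aspect
ratio) are **below the noise floor** here: the core regions hold only
~25 cells and single-run density deviations of ±0.3 are typical, while
the measured core/bulk aspect-ratio contrast (~0.2–0.3 at terminal
density) translates into only a ≲1.2× division-weight excess. The
corresponding tests are expected to fail and are kept failing rather
than loosened; the packing stiffness that sets the aspect-ratio
contrast traces back to print-level ambiguities in the pair-potential
conventions that this package resolves by self-consistency (see the
cell–cell energy section).

## What the synthetic conditions do and do not show

The simulation *is* the object of study here (there is no external
dataset): the generator of record is the seeded initial condition plus
the stochastic schedule above. Passing tests show the implementation
reproduces the model's internal predictions — alignment degrading with
density, ridge crossing suppressed by `k_r`, speeds falling as the
monolayer packs, azimuthal motion around the +1 defect — under the
stated parameters. They cannot show that the model describes any
particular cell line beyond the published calibration, and the
scaled-down box makes defect-core density contrasts noisier than in
the full-size system (the core regions hold only ~25 cells, so
single-run deviations of ±0.3 are typical).

## Known limitations

* Strictly 2D: no ridge height, cell height, or monolayer buckling.
* No extracellular-matrix remodeling and no shape–polarity coupling.
* The division cadence is constant (one division per 100 MCS), not
  fitted to a growth curve; apoptosis and extrusion are absent.
* The ridge width in simulations (4 μm) is a package default, not a
  measured value.
* The one-sided interaction cutoff means energies are not derived
  from a global Hamiltonian; detailed balance holds only in the
  single-cell limit, where the sampled shape distribution is verified
  against Boltzmann quadrature.
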