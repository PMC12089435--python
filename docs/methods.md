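# Methods

## Model overview

The package models sliding-window dynamic MLC delivery of a 2-D optimal
fluence map Φ(x, y), defined on a beamlet grid (1 mm × 1 mm by default)
at the isocenter plane. x is the leaf-travel direction, y the direction
perpendicular to it in the beam's-eye view. The machine is described by
a leaf-pair stack (default Varian Millennium-120: ten 10 mm pairs, forty
5 mm pairs, ten 10 mm pairs, centred so the 5 mm pairs span ±100 mm), a
dose rate (600 MU/min), a maximum leaf speed (25 mm/s), and a total-MU
scaling (500 MU) applied to relative maps — the speed constraint enters
the MU domain as v_MU = v_max · 60 / dose-rate (2.5 mm/MU by default),
i.e. a minimum of τ = dx/v_MU = 0.4 MU per 1 mm beamlet.

Leaves are perfectly absorbing and perfectly focused: no transmission,
leakage, tongue-and-groove or rounded-end penumbra. The delivered
exposure at a point is therefore exactly the MU elapsing while the point
lies inside the open aperture of the pair covering its y band.

## Row-to-pair aggregation

The fluence rows (1 mm) are finer than the leaves (5 mm), so each pair
needs a single 1-D target profile. Two reductions are implemented:

- **max** (default): a pair's profile is the per-column maximum over the
  rows its band overlaps (a row counts when the overlap is ≥ 10 % of the
  row height). The pair opens wherever *any* covered row demands
  fluence. This is the choice that reproduces the characteristic
  over-coverage of real deliveries (conformity index > 1), i.e. exactly
  the behaviour the bank offset corrects; it never under-doses the
  target.
- **coverage_weighted_mean**: overlap-weighted mean, which conserves
  integrated fluence across the reduction but trades target coverage at
  the borders against out-of-field dose. Exposed for comparison; every
  report records which mode was used.

## Sequencing

Per pair, the sliding-window recurrence assigns leaf arrival MUs at the
beamlet centres (leading/right leaf opens, trailing/left closes):

    Δ = Φ(i+1) − Φ(i)
    Δ ≥ 0:  R(i+1) = R(i) + τ,        L(i+1) = R(i+1) + Φ(i+1)
    Δ < 0:  L(i+1) = L(i) + τ,        R(i+1) = L(i+1) − Φ(i+1)
    R(0) = 0, L(0) = Φ(0)

Both branches collapse to the closed form R(i) = i·τ + Σ_{j≤i} max(0,
−ΔΦ_j), L = R + Φ, which is what the code computes; Δ = 0 follows the
Δ ≥ 0 branch by construction. The gap L − R equals Φ at every centre
*by construction* (asserted to 10⁻⁹ MU in tests), both leaves are
monotone, and every per-beamlet step takes at least τ.

All pairs share one global MU clock: the field total is the slowest
pair's final trailing-leaf arrival and early finishers hold closed (no
per-pair time dilation — one beam, one MU counter). Control points are
emitted at every distinct arrival MU, merged within 10⁻⁶ MU; leaf
positions between control points are linear in MU (the standard
constant-speed contract). Each sweep is extended half a beamlet on both
sides (τ/2 on the MU axis each) so the aperture genuinely crosses the
outermost beamlet centres and then closes at the sweep edge; the
extensions stay inside the outer half-beamlets, so consecutive sector
sweeps never overlap spatially.

Sweep direction is fixed left→right. Sector-wise bank offsets are
delivered as consecutive sweeps concatenated on the MU clock; the bank
translation and leaf repositioning happen during a beam hold, modelled
as a pair of control points at the same cumulative MU (the MU axis is
therefore non-decreasing, strictly increasing except at these holds).
The leaf-speed bound applies to every beam-on interval; the hold itself
is instantaneous by assumption, the conservative dosimetric choice since
no fluence is smeared during the move.

## Bank-offset optimization

The map is partitioned along x (the sweep direction — the bank can hold
only one offset at a time, so for a monotone sweep x-sectors and
time-sectors coincide) into 8 equal-width sectors. Per sector, all
candidate offsets from −w/2 to +w/2 in 0.25 mm steps (w = minimum
engaged leaf width; 21 candidates for 5 mm leaves) are scored by
sequencing the sector at that offset, reconstructing the actual fluence
on the 0.25 mm row grid, and taking the mean |actual − optimal| over the
sector restricted to a guard band (the sector's nonzero rows extended
one leaf width up and down — over-coverage lives just outside the
target, and an engaged pair can reach at most one leaf width beyond the
outermost nonzero row), normalized by the sector's mean nonzero optimal
intensity. The difference objective was chosen over the conformity
index because CI is piecewise constant in the offset (threshold-based)
while the difference is a smooth, deterministic argmin; CI is reported
alongside in every comparison.

Ties are broken toward the smallest |offset| (prefer no motion) and then
toward the positive (superior) direction — the direction the bank moves
in the canonical mis-aligned case. All-zero sectors score 0 for every
candidate and keep offset 0. Because offset 0 is always evaluated, the
chosen plan's per-sector objective never exceeds the conventional one,
which makes the whole-map mean absolute difference non-worsening map by
map.

## Delivery reconstruction and oracle

Analytic reconstruction: for each delivery cell the exposure is the
exact MU measure of the time the cell centre lies strictly inside the
open aperture, summed in closed form over control-point intervals (a
leaf moving p0→p1 over ΔMU spends ΔMU·clip((p1 − x)/(p1 − p0), 0, 1)
beyond x). Cell-centre containment is used rather than area-weighted
partial coverage — at 1 mm beamlets and 0.25 mm rows partial-x coverage
is second order; it is the documented refinement candidate. The
delivery grid's row height is the candidate step (0.25 mm), so every
admissible bank offset lands on grid lines.

The brute-force oracle marches the MU clock in fixed steps, sampling
leaf positions at step midpoints. Its per-cell error is bounded by twice
the step; empirically the maximum deviation tracks ≈ 0.9× the step
(first-order convergence — note a *single* halving of the step
therefore gives a deviation ratio of ≈ 0.5, not robustly below it).
The oracle exists only to cross-check the analytic route in tests.

## Metrics

All comparison metrics are computed on the 0.25 mm row grid (the
planned map row-replicated ×4) so sub-leaf offsets are not aliased.
"Irradiated" means exceeding τ = 0.1 of the planned map's maximum (a
conventional field-edge surrogate; the paper-style CI definition leaves
the threshold open, so every report records τ). CI = actual/planned
irradiated area; out-of-field area counts cells irradiated where the
plan is not; mean absolute difference is normalized by the mean planned
intensity over the planned support and averaged over the union of
planned and actual supports; mean intensity is averaged over the same
union support (symmetric between techniques). Paired comparisons use
the two-sided paired t-test, with degenerate inputs (all-zero or
constant differences) mapped to (0, 1) and (±∞, 0) explicitly.

## Synthetic data

Clinical optimal fluence maps are not redistributable, so suites are
generated: modulated ellipses (blob-like tumour cross-sections with
smooth intensity texture from seeded, Gaussian-smoothed noise rescaled
to [1 − depth, 1], depth ~ U[0.1, 0.4]) in two size regimes — *small*
(y extent U[20, 30] mm, x extent U[30, 50] mm; head-and-neck/lung
scale) and *large* (y extent U[60, 80] mm, x extent U[60, 80] mm; liver
scale). The key randomized parameter is the target bottom edge's phase
relative to the 5 mm leaf boundaries, uniform over [0, 5) mm: the whole
benefit of the bank offset lives within one leaf width of the border,
so a fair suite must sample every phase. Each map gets its own grid
(target + 10 mm x-margins, 15 mm y-margins) centred in the fine 5 mm
leaf region. Rectangles, two-lobe shapes and pure-noise modulation are
available for calibration and edge-case tests; the canonical worked
rectangle (y ∈ [2.5, 27.5)) lives on a half-integer grid because a
1 mm beamlet lattice cannot represent half-millimetre edges otherwise —
for the same reason suite maps realize their drawn edge phase rounded
to the row lattice, exactly as 1 mm clinical beamlet maps would.

What the generator does *not* emulate: TPS-optimized fluence textures
(dose-gradient-driven, not smoothed noise), island/concave targets,
multi-field context, or absolute dosimetry. Passing suites therefore
demonstrate the geometric/sequencing properties of the technique — the
border effect, its dilution for large targets, delivery exactness — not
clinical dose improvements.

## Problem sizes and defaults

Suite evaluations use 50 maps per regime; the oracle cross-check uses
20 (tests) / 10 (acceptance script) end-to-end fields at 20 MU total
with a 0.01 MU step. Defaults throughout: 8 sectors, 0.25 mm candidate
step, τ = 0.1 threshold, `max` aggregation, ×4 row upsampling, 500 MU
scaling at 600 MU/min with 25 mm/s leaves.

## Known limitations

- Zero leaf transmission: absolute out-of-field values are lower bounds;
  relative comparisons between techniques are unaffected since leakage
  acts as a common additive background.
- Cell-centre containment in x (no partial-cell coverage).
- No interdigitation/minimum-gap/carriage constraints, no dose-rate
  modulation, no step-and-shoot mode.
- Sector optimization is per-sector independent (no joint search), and
  the sweep direction is fixed.
- A pair whose profile is nonzero at the very last grid column never
  fully closes within the modelled sweep; fixtures keep a zero border.
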