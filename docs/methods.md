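# Methods

## The mechanical model

The tissue is a single row of quadrilateral cells sharing two ordered
vertex chains — luminal (facing the duct lumen) and basal (on the basement
membrane). A cell polygon occupies its basal footprint even when its
nucleus is luminal, so one polygon represents the averaged cellular
material at a position along the apex-base axis rather than a literal cell
outline. Vertices obey overdamped dynamics

η(ṙᵢ − vᵢ) = −∇ᵢU,

where vᵢ is the local velocity — the mean of the centroid velocities of
the cells containing vertex i — and

U = Σⱼ [k_a/2 (aⱼ−aⱼ*)² + k_b/2 (bⱼ−bⱼ*)² + k_l/2 (lⱼ−lⱼ*)²
  + k_A/2 (Aⱼ−Aⱼ*)²] + Σᵢ k_θ/2 θᵢ².

aⱼ, bⱼ are the cell's luminal/basal edge lengths, lⱼ the mean of its two
lateral edge lengths (assigning the lateral energy per cell without
double-counting shared edges; a per-edge variant is one flag away), Aⱼ the
shoelace polygon area, and θᵢ the deviation-from-straight (turning) angle
of each chain at its interior vertices — chain endpoints carry no bending
energy, so a straight chain has zero bending cost.

### Cell cycle and nuclear depth

Each cell carries a timer τ ∈ [0, τ_div] with phases G1:S:G2:M partitioned
11:8:4:1 (boundaries at 11/24, 19/24, 23/24 of τ_div). The nuclear depth
d ∈ [0, 1] (0 = luminal) is piecewise linear in τ:

- d = 2γ τ/τ_div for τ ≤ 0.5 τ_div (basalward excursion to γ),
- d = (0.95 − τ/τ_div)·γ/0.45 for 0.5 τ_div < τ ≤ 0.95 τ_div (return),
- d = 0 thereafter (luminal through mitosis),

continuous at both breaks. γ ∈ [0, 1] is the degree of basalward return:
γ = 1 is full interkinetic migration, γ = 0 complete luminal stalling. The
depth drives the edge targets linearly between ξ_max and ξ_min,
a* = (ξ_min−ξ_max)d + ξ_max and b* = (ξ_max−ξ_min)d + ξ_min, so a* + b* is
conserved and a luminally-stalled cell (d = 0) demands a long luminal and
short basal edge — the local bending moment behind the whole study.

At τ = τ_div the cell splits at the midpoints of its luminal and basal
edges; one daughter restarts at τ = 0 and the other at a uniform offset in
[0, 0.1 τ_div] (assigned to a random side) to desynchronize neighbours.
Initial phases are uniform on [0, τ_div).

### Parameters (standard set)

| parameter | value | meaning |
|---|---|---|
| η | 1 | viscosity (unit mobility) |
| k_a, k_b, k_l | 1 | edge-spring coefficients |
| k_A | 0.01 | area-preservation coefficient |
| k_θ | 30 | bending rigidity |
| A* | 125 µm² | target area (2.5 × 50 µm initial cell) |
| l* | 50 µm | target lateral (layer thickness) |
| τ_div | 432 | cycle length (⇔ 24 h; 1 h = 18 units) |
| γ | 0.9 | basalward return degree |
| ξ_max, ξ_min | 5, 1 µm | edge-target range |
| dt | 0.01 | forward-Euler step |

Initial condition: 20 rectangles, 2.5 µm × 50 µm, in a horizontal row with
the lumen above. Lengths are µm; forces are energy/µm; time is in
simulation units.

### Numerics

Forward Euler at dt = 0.01. The local-velocity coupling makes the equation
of motion implicit (velocities on both sides); the production scheme lags
vᵢ one step (zero at t = 0), which matches explicit Euler stepping. The
implicit system is singular along rigid translation — a uniform velocity
satisfies v(ṙ) = ṙ — so the opt-in validation solver (`step_implicit`,
fixed-point iteration) pins the mean vertex velocity to the force-driven
value; the two schemes agree on centered shapes to < 0.05 µm over hundreds
of steps while the translation mode (pure gauge for tissue shape) differs.
A by-product of the lagged scheme is a persistent center-of-mass drift;
it does not affect any measured quantity. Analytic force expressions for
every energy term are verified against central-difference gradients of the
potential (relative error < 10⁻⁵). Forward Euler is stable at dt = 0.01
for the standard stiffnesses; strongly stiffened variants (e.g.
k_A = 10³, area-mode stiffness ≈ k_A (h/2)²) need dt below ~10⁻⁶ and are
tested at such steps. Chain self-intersection is checked at event
boundaries via polyline simplicity and aborts the run with a diagnostic.

Between cell-cycle events (a division, an arrest-window entry, the arrest
onset) timers advance deterministically, so the driver computes the exact
step count to the next event and integrates the mechanics in one compiled
(numba) chunk — event handling is exact to within one dt. All stochastic
draws flow through a single seeded generator; replicate seeds derive from
the master seed by a fixed (seed, stream, replicate) counter, so results
are independent of execution order and bit-reproducible.

## Virtual experiments

**γ sweep.** Uniform cycling (all cells τ_div = 432, no stalling, no
arrest), 10 replicates per γ, each run to 80 cells (≈ two cycles). The
stop condition is a package choice: at ~one cycle the interior curvature
has not yet developed (bending is still boundary-localized) and the γ
ranking is not yet stable; by two cycles it is. The scalar readout is the
mean signed curvature over interior profile samples (two 15 µm samples
trimmed at each end, where one-sided spline windows are least reliable).

**Developmental control.** A luminal-stalling region of arc length L from
the apex end of the luminal chain: daughters of cells dividing inside it
never re-enter the cycle (timers frozen, nuclei luminal). Non-stalled
daughters redraw τ_div ~ U(216, 864). Runs stop when the cell count
reaches 100. L is never printed in the source material; it was
reconstructed once from the two printed simulation outcomes (mean control
duration ≈ 1298 and the arrest contrast below) over a coarse sweep
L ∈ {15, 20, 25, 30} µm and frozen at **L = 20 µm**; it is reported in all
experiment metadata. Larger L lengthens runs but lets the apex curl
persist in the arrest arm; smaller L weakens the apex curl.

**Cycle arrest (MMC).** Identical to the control, plus: once t > 700,
any cycling cell whose timer sits in [0.25, 0.8] τ_div (mid-G1 through S)
is frozen; cells below the window freeze on reaching 0.25 τ_div, cells
beyond it divide once more and their daughters freeze on entry. Evaluated
at t = 1300. Arrested nuclei are dispersed across depths (d between ~0.3
and 0.9), which removes the luminal-stalled bias and flattens the layer.
The arms are compared by two-sided Mann–Whitney U on the 10-vs-10
replicate mean curvatures. The effect direction is highly reproducible;
its p-value at N = 10 sits near the 10⁻³ decision point and varies with
the master seed, because the arrest arm freezes chain micro-buckles that
the cycling control keeps remodelling away (this is replicate shape
variability, not measurement noise).

## Morphometrics

The midline is the geometric mid-curve of the traced luminal and basal
polylines: each luminal point is paired with its nearest point on the
basal polyline and midpoints are taken (the image-skeleton step of the
original pipeline replaced by its geometric analogue, since inputs here
are polylines). The raw mid-curve is lightly smoothed (moving average of
half-width 4 µm at 1 µm resolution — well below the 15 µm sampling scale;
configurable) to suppress point-to-point zigzag, resampled at 15 µm arc
spacing, and interpolated by natural cubic splines of x(s), y(s).

Curvature per sample uses the per-interval cubic formula
κ(x) = (6a(x−xᵢ)+2b)/(1+{3a(x−xᵢ)²+2b(x−xᵢ)+c}²)^{3/2} evaluated in a
local frame: a 7-sample window is rotated so the local tangent is the
abscissa and an interpolating cubic spline y(x) with not-a-knot ends is
fitted. Two numerical choices matter here and were validated on analytic
arcs: a 5-sample window has an intrinsic ≈6% low bias at κ·spacing = 0.3
(R = 50 µm), and natural end conditions on a short window force y″ = 0 at
the window edges, biasing the central curvature by ≈5/6 on a parabola —
hence 7 samples and not-a-knot for the windows (the global parametric
spline stays natural). A parametric curvature
κ = (x′y″−y′x″)/(x′²+y′²)^{3/2} on the same spline serves as an internal
oracle; the two agree within 2% away from the curve ends. The recovery
bound (mean error < 5% for R ∈ {50, 100, 200} µm at 15 µm sampling) is
met with margin except exactly at the κ·spacing = 0.3 validity edge,
where it is ≈2.5%.

Sign convention: κ > 0 where the layer is convex toward the lumen, i.e.
the osculating-circle center lies on the basal side (decided per sample by
the cross product of the local tangent with the midline→luminal vector).
Consequence: a circular layer enclosing its lumen has κ < 0, and the
γ = 0 virtual tissue — which curls away from its lumen — has κ > 0.

Thickness at a sample is the length of the perpendicular segment clipped
between the two edge traces; where the perpendicular misses an edge (near
trace ends) it is NaN. The flat/curved split takes the half-maximum of the
(3-sample moving-average; configurable, the original work states none)
smoothed |κ| and returns the first crossing s\* by linear interpolation;
constant profiles are flagged degenerate. Arc lengths are measured along
the full raw mid-curve from the projection of the apex tip, which must
project near an end of the midline.

First/last profile samples are fitted with one-sided windows and are the
least reliable on noisy traces; summaries trim them and the examples
classify interior samples.

## Synthetic data

The original traces are not deposited, so generators stand in with known
ground truth. Layer traces: a midline integrated exactly (per-step
circular-arc chords) from piecewise-constant prescribed curvature, offset
by ± thickness/2, with i.i.d. isotropic Gaussian noise on trace points —
a model of manual-tracing error (default 1–2 µm, plausible but
unvalidated), not of optics; no point-spread, shading or segmentation
artefacts are emulated, so passing tests certify the geometry pipeline,
not robustness to imaging pathology. Nuclear tracks: d(τ) evaluated on a
flat layer with uniform random phase offsets, observed at fixed intervals
(1 h = 18 simulation units), noise added to positions; γ is recovered as
the mean per-cell maximal basal excursion over the thickness. Division
events: true (φ, θ) sampled (|N(0, σ_φ)|; axial von Mises or uniform
azimuth), embedded in uniformly random rigid frames; at zero jitter the
orientation module recovers the truth to machine precision.

## Known limitations

- Tissue ends are force-free with no bounding window; the finite-window
  boundary condition of the original study is unquantified and off by
  default (`Simulation` exposes no wall), which plausibly shifts absolute
  curvature values — relative comparisons are the meaningful output.
- The vertex chains micro-buckle at cell scale under edge-target mismatch;
  per-sample curvature of simulated tissues carries ±0.005–0.01 µm⁻¹
  ripple that only averages out in profile means.
- Single cell row: no T1 transitions, no 3D effects, no explicit nuclear
  particles.
- The Mann–Whitney exact branch requires C(n_a+n_b, n_a) ≤ 2×10⁵ and no
  ties; otherwise the normal approximation (tie + continuity corrected) is
  used and recorded in the result.
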