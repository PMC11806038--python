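# Methods

This note documents the models, conventions, numerical choices and
limitations of `wingshear`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and angles

Positions are stored in image coordinates (x rightward, y downward, µm;
origin at the image top-left), because that is how segmented microscopy
arrives. Every reported angle, however, is mathematical — counterclockwise
from +x after flipping the y-axis — and every orientation (junctions,
polarity axes, flow directions) is an *axial* quantity defined modulo 180°,
stored in [−90°, 90°). Axial statistics use doubled angles throughout. The
PD (proximal-distal) axis is identified with +x ("proximal left" image
orientation); flow sign never matters because the headline gradient
statistics are means of absolute values.

## Tissue velocity gradient

Per-cell velocities are forward differences of tracked centroids over one
acquisition interval (default 15 min, the cadence of the source time-lapse
protocol), with no trajectory smoothing — the statistic is meant to be
instantaneous at that cadence.

Coarse-graining uses a square grid whose pitch is c·√(mean cell area); c is
adjusted by bisection until the realised *median* occupancy of non-empty
elements lands in the target band — 1–2 centroids per element in fine mode
(c ≈ 1.2), 2–4 in coarse mode (c ≈ 2.4, used for heatmap-style local
analyses). Each cell joins the element nearest its centroid; points exactly
equidistant between elements go to the lexicographically smaller (i, j).
An element's position is the mean of its member centroids (not the
geometric grid centre) because the finite-difference denominators divide by
data positions; a geometric-centre mode exists for comparison. Element
velocity is the plain mean of member velocities.

The 2×2 velocity-gradient tensor per element uses *forward* differences to
the (i+1, j) and (i, j+1) neighbours. A component is valid only if the
forward neighbour exists, is non-empty, and the coordinate denominator
exceeds pitch/10 (guards against near-coincident element positions).
Invalid components are masked, never zeroed; aggregation averages only
valid magnitudes. On an affine (uniform/shear/rotation) flow this
discretisation is exact up to the cross-contamination term
A_other · Δother/Δprimary, which vanishes for a shear aligned with the
grid and shrinks with grid size otherwise — the reason the rotation-
equivariance check is run on a 24×24-cell sheet.

The flow direction is the nematic mean of cell velocities weighted by
*squared* speed, (v̄ₓ, v̄_y) = n⁻¹ Σ |vₖ|²(cos 2φₖ, sin 2φₖ). The default
axis is the half-angle θ = ½·atan2(v̄_y, v̄ₓ), which returns the correct
axis for pure flows at any angle (e.g. 45°); a `theta_literal` flag instead
applies arctan(v̄_y/v̄ₓ) directly to the doubled-angle vector — that
formula is dimensionally a 2θ quantity and is provided purely for
comparison with the printed definition. Which variant produced the original
published numbers is not determinable, so both are exposed; the default is
chosen for correctness. In AP mode the axis is rotated 90° (axial) so the
reported off-diagonal refers to anterior-posterior flow.

Tensors are expressed in the flow frame by conjugation with R(−θ) (the
rotation taking lab axes onto flow axes); the tissue-wide gradient is the
mean |off-diagonal| over valid elements. Diagonal aggregates are computed
but only diagnostic — in the source data they showed no condition
differences and no relation to protein stability. θ is estimated once per
averaging window (default 2 h = 8 intervals) from all samples in the
window; window averages are arithmetic means of the instantaneous values.
A fully stationary window has an undefined flow direction; θ is then set
to 0, which is immaterial because every tensor is zero.

## Polarity estimator

Per-cell polarity is the intensity-weighted second moment of unit
directions from the cell centroid to its boundary pixels,
M = Σ wₚ uₚuₚᵀ / Σ wₚ, with magnitude (λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1] and axis
along the leading eigenvector. For a circular cell painted
I(φ) = 1 + A cos 2(φ−φ₀) the closed form gives magnitude exactly A/2 at
axis φ₀, which is the calibration the tests pin. Shape normalisation
(default on) whitens boundary positions by the inverse square root of the
unweighted shape covariance, removing the bias of elongated cells toward
their long axis; the exact normalising transform of the original
polarity-analysis tool is not published, so this whitening is this
package's own formalisation. A junction-midpoint variant
(`polarity_from_junctions`) serves table-level pipelines that have no
per-pixel boundary samples.

Polarity-angle variance is the axial circular variance
V = 1 − |mean e^{2iφ}|, *unweighted* across cells (a magnitude-weighted
option exists; whether the published variance was weighted is unstated).
Circular histograms duplicate each axial angle at φ and φ+180°, use 20
half-open 18° bins, and weight each bin by count × mean member magnitude.
Eccentricity is √(1 − λ₂/λ₁) from the unweighted second moment of member
pixels.

## Timer stability and junction dynamics

The tandem timer couples fast-maturing sfGFP (channel 1) and slow-maturing
mKate (channel 2); the ratio S = mKate/sfGFP rises with the long-resident
protein fraction. Two conventions coexist in the protocol and both are
implemented, keyed by scope: population scopes (wing, junction class) pool
*summed* junctional intensities (a total ratio, not a mean of per-junction
ratios — the tests pin the difference); single-junction S uses the ratio of
*mean* intensities (the sliding-junction protocol). S is strictly relative:
it depends on acquisition settings and is never inverted into absolute
residence times.

Junctions are classified against the flow axis: within ±45° (exclusive) is
"horizontal" (flow-parallel) in PD mode; AP mode swaps the band. The
|Δ| = 45° boundary goes to the "otherwise" class, reading "between −45° and
+45°" as an open interval. The reference axis defaults to the measured
window flow direction; a fixed-PD mode exists for rotational-flow controls
where the instantaneous axis is meaningless.

T1 detection diffs tracked adjacency between consecutive frames: a gained
edge C–D paired with a lost edge A–B whose quartet was mutually adjacent
beforehand. The gained edge must persist to the end of the observation or
for a persistence horizon (default 4 frames = 60 min — the source protocol
says only "stable over time", so this is a package choice, configurable),
must not revert, and must not itself be the restoration of a recently lost
edge. Multi-candidate rosettes are flagged ambiguous, not resolved.
Sliding junctions are 4-way → 3-way vertex-degree transitions between
consecutive frames; vertex degrees come from the labels within a 2-px
radius of each junction endpoint (raster path) or from the tracked tables.
Post-T1 accumulation profiles and the sliding-vs-control stability
comparison use the percent-change metrics (X_t − X₀)/X₀ × 100 with t₀ at
new-junction formation (T1) or the pre-movement frame (sliding).

No background subtraction is applied to junction intensities by default
(the FRAP path subtracts background explicitly); a constant per-channel
offset option exists at normalisation time in the FRAP module only.

## Ablation and FRAP

The wound-recoil model: a circular ablation ROI (protocol radius 5 µm)
recoils into an ellipse; `fit_ellipse` is a direct least-squares conic fit
(scikit-image's estimator — the original fit method is unstated), returning
semi-axes with a ≥ b enforced. Initial recoil velocities are
(a(t) − r₀)/t and (b(t) − r₀)/t at the first post-ablation frame by
default (60-s cadence); a 120-s snapshot mode matches the figure protocol.
Whether the published velocities used one frame or an early-frame
regression is unstated; both single-time evaluations are exposed.
v_a = (v_maj − v_min)/2.

FRAP traces are background-subtracted, normalised to the pre-bleach mean,
and fitted with F(t) = F₀ + (plateau − F₀)(1 − e^(−kt)) by
Levenberg-Marquardt least squares (k bounded positive; initial guesses from
the first/last samples). Fits with R² below 0.5 are flagged — a stand-in
for the commercial lack-of-fit exclusion test. The fit is invariant to the
post-bleach time origin and to uniform gain. An optional mono-exponential
acquisition-bleaching correction from a reference region is not applied by
default.

## Synthetic tissue generator

The generator defines the study conditions; it is not a tuning dial. A
jittered hexagonal lattice (default jitter 0.15 of the spacing, mean cell
area 16 µm² — typical apical areas at these stages) becomes a Voronoi
polygon mesh; the outermost ring pads the tracked interior. Topology is
frozen (perfect tracking) and all vertices are advected by the imposed
kinematic flow with Euler steps at the acquisition interval (15 min,
frames starting at 24 hAPF) — no sub-stepping, matching what the
measurement cadence can see; a mesh inversion under a too-stiff flow
aborts. Flow speeds default to ~0.1 µm/min, an order-of-magnitude choice
(no measured speeds are printed in the source text); shear rates span
0.002–0.02 min⁻¹ in the multi-wing experiments. Optional centroid jitter
models tracking noise without touching geometry.

Channel painting: sfGFP carries the polarity pattern
I₁ = base(1 − m cos 2(φ_j − φ_pol)) — a polarity *axis* φ_pol means
enrichment on junctions oriented perpendicular to it, so a
centroid-to-boundary estimator recovers φ_pol — plus additive Gaussian
noise (σ relative to base, the simplest model supporting SNR sweeps;
negative draws are clipped at zero and counted). mKate is s_j · gain · I₁
with the stable fraction s_j reduced by β·|local ∂v′ₓ/∂y′| on
flow-parallel junctions (clamped at 0). Injected sliding events multiply
mKate by (1 + effect/100) from their post-frame, with the default effect
−24% and an optional compounding per-interval control drift (the
corresponding measured control change was +10%); injected T1 events grow a
new orthogonal junction from the old midpoint and persist without
reverting. All event schedules, couplings and noise levels are exported as
ground truth, sufficient to score every detector and estimator in the
package.

What the generator does *not* emulate: mechanical force balance (flows are
kinematically imposed, not emergent from a vertex model), cell divisions
and extrusions, segmentation errors and tracking identity switches,
rosettes, spatially correlated intensity noise, and acquisition
photobleaching. Passing tests therefore demonstrate the correctness of the
quantification machinery under controlled kinematics and its calibration
against closed forms — not robustness to segmentation pathology in real
microscopy.

## Problem sizes and numerical defaults

The test and acceptance runs use sheets between 8×8 and 40×40 lattice
cells (36–1444 tracked cells), 2–10 frames, and Monte-Carlo loops of 20
seeds — sizes chosen so each check isolates one property at comfortable
numerical margins. Key tolerances: grid denominators > pitch/10;
eigen-decompositions via symmetric solvers; tie-breaks lexicographic;
degenerate inputs (all-zero velocities, zero total intensity, collinear
boundaries, constant FRAP signals) raise or flag rather than return
silently wrong numbers.

## Known limitations

- Forward differences leak a cross-term on coarse grids when the flow axis
  is oblique to the grid; fine-mode occupancy and larger fields mitigate it.
- The literal doubled-angle flow-direction formula is reproduced only
  behind a flag; results with it differ for oblique flows by construction.
- Junction endpoint recovery on rasterised skeletons is approximate near
  image borders (open-ended junctions fall back to extreme pixels).
- Event detectors formalise what was originally manual annotation;
  persistence horizon and vertex tolerance have no published values and
  are configurable package choices.
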