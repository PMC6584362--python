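# Methods

## The tissue-length model

The plate is idealized as a rectangle of `N = n·m` cells with rows running
along the proximo-distal (PD) axis. Tissue anisotropy is the count ratio
`σ = n/m`, so the number of cells spanning the length is `n = √(Nσ)` and
the plate length is `L = √(Nσ)·Lc`. Each cell is replaced by its
moment-equivalent ellipse of area `a` and axis ratio `s`, whose full axes
are `l₁ = 2√(a/πs)` and `l₂ = 2√(as/π)`. Because roughly half of the cells
have their long axis along PD, the mean PD extent per cell is taken as the
average of the two axes, `Lc = √(a/πs) + √(as/π)`, giving
`L = √(Nσa/π)(√s + 1/√s)`. The model's assumptions — rectangular packing,
ellipse-equivalent cells, a 50/50 orientation split — make it an estimate,
not an exact identity; on its own idealized tessellation (s ≈ 1) it
reproduces the generated plate's PD extent within ~5% (tested at 10%).

Between-species transformation uses coefficients `k = target/reference`
per parameter. Because `L` is a product of powers of `N, σ, a` times a
function of `s`, applying the full coefficient set to the reference
parameters reproduces the target length exactly; partial subsets quantify
contributions. The shipped published coefficient set keeps
`k_s = 0.9363` as a constant even though the rounded tabulated shape
values (1.57 for both species) would give 1.0: the original value was
computed from unrounded data that only exists upstream of the printed
tables, and reproducing the decomposition requires it verbatim.

## Synthetic tessellations

`generate_hex_plate` builds a brick-offset hexagonal tessellation from a
single shared vertex pool, so the tiling is exact by construction (cell
union equals the footprint to rounding error) and remains exact under
vertex jitter. Each hexagon has a fixed width `w`, two vertical edges of
per-row length `e_j`, and zigzag caps of global amplitude `δ`.

Shape and orientation control. A global affine cannot give two cell
populations different elongation axes while they share vertices, so
orientation is assigned per row: exactly `round(f·m)` rows (shuffled;
`f` = `aligned_fraction`) are "PD-aligned". For each class the vertical
edge length is solved (Brent root-finding on the exact polygon moments) so
the hexagon's second-moment ratio equals `s²` along PD (aligned rows) or
DV (non-aligned rows); the moment-ellipse ratio of every cell is then
exactly `s` with orientation 0° or 90°. A quota rather than i.i.d.
Bernoulli assignment keeps the realized aligned fraction at the target
even for plates of a few dozen rows. The cap amplitude shrinks from the
regular-hexagon value 0.5 only when large `s` demands it (`δ =
min(0.5, w/2.5s)` in lattice units); at `s = 1`, `noise = 0` the output is
a regular hexagonal tiling. One global isotropic rescale pins the realized
mean cell area to `cell_area` exactly; aligned and non-aligned rows then
differ in area (by construction of the two row heights), which is the
price of holding `w` global — the mean is exact and the spread is
tissue-like.

`orientation_noise` (degrees) jitters every shared vertex with an
isotropic Gaussian of sd `0.8·noise` in radians times the lattice
half-size, clipped to 45% of the smallest local edge scale so rings stay
simple. The mapping to realized angular scatter is approximate by design;
parameter-recovery tests bound its effect (area 2%, shape 5%, σ 10% at
5° noise).

Transect counting. Rows/columns are counted on three lines at fractional
positions of the plate's DV/PD extent (default 0.25/0.5/0.75). Each line
is snapped to the nearest cell-centroid coordinate and nudged by 1e-9 of
the extent: on a regular tessellation the raw fractional positions land
exactly on shared vertices or edges, where "any intersection" counting
would double the count. A cell counts when the chord through its interior
exceeds 15% of `√(mean area)`, so grazing contacts at junctions (and their
jittered descendants) are not row membership. Counts are kept as real
numbers (means of three transects); `σ` is their ratio.

Growth series. Within a phase, each frame scales the tissue isotropically
by `multiplier^(1/duration)`; scheduled row/column count changes are
spread over the phase by rounding the linear interpolant (monotone by
construction) and realized by rebuilding the lattice at the new counts and
current area — margin insertion/removal, since the lattice has no interior
history to preserve. The per-frame ground truth (`n, m, σ = n/m, a`) is
returned alongside the plates. The study-window preset used in tests and
examples runs 36 → 45 rows, 38 → 29 columns and ×2.2 area over 9 frames,
matching the reported +25% rows, −24% columns and the area trajectory of
the 36–54 h APF window; σ then rises 0.95 → 1.55 strictly monotonically.

T1 realization. Scripted events pick interior lattice edges whose four
incident cells are pairwise disjoint from other events' quartets. The flip
collapses the shared edge to its midpoint and re-extends a new edge (30%
of the collapsed length) along the losing pair's centroid axis, reusing
shared vertices so the tiling stays exact; the losing cells retain single
point contacts, which the neighbor graph correctly ignores. Stable events
flip once at a random frame and persist; oscillating events revert before
the last frame. On a hexagonal lattice the gaining pair's centroid line
can only realize the three lattice axes (≈30°, 90°, 150° from PD), so
scripted von Mises draws select the admissible edge nearest each drawn
angle and the ground truth records the realized centroid angles.

## Morphometrics

Areas and second moments are computed exactly over the polygon interior
(Green's-theorem formulas), never from vertex scatter or pixels, making
them resolution-free and deterministic. The fitted ellipse is the
second-moment-equivalent one (full axis `4√λ` per covariance eigenvalue),
the same object a raster tool's region properties converge to with
infinitesimal pixels — tests verify 1% agreement against a
pixel-second-moment oracle. For a polygon that is itself an ellipse this
recovers its axes (and hence its area) exactly. Orientation is axial
(mod 180°), measured from the per-plate PD axis; a cell is "PD-aligned"
when the acute angle is strictly below 45° (the boundary counts as
non-aligned). The corrected total count extrapolates the segmented density
into un-segmented plate area: `N = n·A_total/A_seg`.

## T1 detection

Neighbors are cells sharing boundary length above 1e-6 μm (point junctions
excluded; overlap raises a geometry error). Between consecutive frames, a
lost contact (A,B) paired with a gained contact (C,D) is a T1 when the
four tracks are distinct and C, D were each neighbors of both A and B
before the exchange; the event is attributed to the first frame with the
new contact and its angles are measured there. Stability is resolved per
quartet against the start of the acquisition: if the quartet's final
configuration equals its initial one, every exchange in it is oscillating
— a per-event reading would misclassify the reverting flip of an
oscillation as a new stable event. Cells whose track disappears across an
exchange frame cause that candidate event to be skipped rather than
guessed.

## Allometry

SMA slope is `sign(r)·sd_y/sd_x`; the CI uses the standard pivot
`b·(√(B+1) ± √B)`, `B = (1−r²)F(conf; 1, n−2)/(n−2)`. The common-slope
test maximizes the SMA profile likelihood in `b` (bounded search between
the group slopes, tolerance 1e-10) using each group's correlation between
residual (`y − bx`) and axis (`y + bx`) scores, and refers
`−Σ nᵢ log(1−rᵢ²(b̂))` to χ² with `groups − 1` df. Calibration is verified
by simulation: type-I error 0.049 at nominal 0.05 (1,000 reps), CI
coverage 95.5% at nominal 95%.

The allometry generator scatters points about the group line with total
vertical sd `noise_sd`, split between the two coordinates with error-sd
ratio equal to the slope (`σ_y,err = |b|·σ_x,err`). This is the error
structure under which SMA is the consistent estimator and mirrors
trait/size data in which both axes are measured quantities; putting all
noise on `y` would make the SMA slope converge to
`√(b² + (σ/sd_x)²)` — a structural bias of ~3.5% at the default study
conditions — and is therefore not what this generator emulates. The latent
size spans 0.4 decades (a ~2.5-fold size range, as produced by diet
manipulation); intercepts and slopes are per group, and `noise_sd = 0`
reduces to exact lines.

## Problem sizes and determinism

All stochastic operations take explicit integer seeds; identical inputs
give bitwise-identical outputs. The test suite and acceptance script
exercise plates up to 45×29 cells (1,305 polygons), 50 random T1 scripts
on 14×10 plates, 391-event nematic samples over 100 seeds, and 200–1,000
Monte-Carlo replicates for the SMA calibration — sizes chosen to give
stable statistics at interactive runtimes.

## Limitations

- The tessellation is an idealization: no curved plate margins, bristle
  rows, folds or segmentation artifacts; passing round-trip tests shows
  the measurement chain is self-consistent, not that segmentation of real
  images is accurate.
- Orientation is bimodal (0°/90° plus jitter) rather than continuously
  distributed, and per-row rather than per-cell; the aligned fraction and
  mean shape are faithful, the full orientation distribution is not.
- Growth series rebuild the lattice when counts change, so per-cell
  identity is not preserved across count-changing frames (tracked
  identities are the T1 generator's job).
- The length model's percent-of-measured comparison requires a measured
  reference length supplied by the user; no measured plate lengths ship
  with the package.
- No mechanics: forces, cell autonomy and apoptosis are out of scope.
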