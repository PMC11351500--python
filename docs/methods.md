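# Methods

## The measurement problem

Near-infrared (≈850 nm) imaging of the forearm shows superficial veins as
dark tubular structures on brighter tissue, because hemoglobin absorbs more
NIR light than skin, muscle or bone. Vessel caliber in such images is a
clinically useful quantity (e.g. for planning and monitoring hemodialysis
vascular access), but raw NIR frames are blurred, noisy and low-contrast,
and vessel width varies along the vessel, so a single-profile measurement is
unreliable. `veinwidth` estimates the mean lumen width of a vessel segment
from a single-channel 8-bit image (nominally 100 × 100 px) by combining a
one-pixel centerline, a one-pixel edge map, and a per-centerline-point
tangent-circle radius search.

## The width estimator

At every skeleton point *i* a circle centered on that point grows in
discrete radius steps (default 1 px) until it first touches an edge pixel;
the first-contact radius is *r_i* and the local diameter is

    d_i = 2 r_i − 1,        D = (1/n) Σ d_i

with *D* the segment's mean width over the *n* skeleton points. Distances
are true Euclidean distances between pixel centers, so for integer steps
*r_i* equals the ceiling of the nearest-edge distance — the package carries
an independent exhaustive-scan oracle (`retc_oracle`) and tests exact
equivalence with the radius-growth loop.

The "−1" in *d_i* encodes an edge-placement convention: the edge pixel sits
one pixel **outside** the lumen (the first background pixel), so the lumen
spans the pixels strictly between opposing first contacts. For a straight
band of odd width *w* with a centered skeleton, the nearest outside edge is
at distance (w+1)/2, giving *d = w* exactly; with edges on the outermost
lumen pixels instead, *d = w − 2*. This pair of identities pins the
convention and is regression-tested. The package-wide default is therefore
`edge_offset="outside"`. Skeleton points whose circle reaches `r_max`
(default: the smaller image dimension) without touching an edge — e.g. a
spur pointing into an edge gap — are excluded from the mean and counted,
rather than aborting the run.

## Pipeline stages

**Preprocessing** (fixed order: crop → stretch → median → stage-1 enhance →
CLAHE). The automatic crop finds the arm as the largest bright component
above an Otsu threshold, closes over vessel-width gaps (vessels crossing the
arm must not split it), fills holes, pads the bounding box by a 3 px margin
and flattens non-arm pixels to the component-border median. Contrast
stretching maps the 1st–99th intensity percentiles to 0–255 (percentiles,
not min/max, so hot pixels cannot collapse the range). Median filtering
(3 × 3, edge replication) removes shot noise without blurring edges. The
first enhancement stage is a pluggable slot for a learned residual enhancer;
the built-in stand-in is unsharp masking (amount 1.0, σ 2.0), and the stage
can be disabled or pointed at a user-supplied model. CLAHE runs with an
8 × 8 tile grid and a clip limit of 0.01 of the tile pixel count (clip
expressed as a fraction so it is resolution independent); these are
conventional values — no canonical setting exists for this imaging setup.

**Segmentation.** The vessel contour is the zero level of a field φ
(negative inside) evolved under a distance-regularized edge-based flow. The
edge indicator g = 1/(1 + |∇(G_σ ∗ I)|²) is computed on the 0–255 intensity
scale with σ = 1.5 px; on that scale a vessel edge drives g toward zero
while flat tissue keeps g ≈ 1. (On a unit-normalized image the squared
gradient at an edge is ~0.04 and g never drops below ~0.96, which lets the
balloon force inflate far past the vessel — the 0–255 convention of the
standard distance-regularized schemes is the working choice here.) The
Dirac smoothing δ_{2,ε} uses the compact-support cosine form with ε = 2.
Initialization is a rough segmentation taken literally: Otsu on the inverted
image, 3 × 3 opening, components below 30 px dropped, φ the signed distance
to the rough boundary. Evolution uses dt = 1.0, regularization weight
μ = 0.2 (μ·dt < 0.25 for stability), length weight λ = 5, balloon weight
α = −1.5 (negative expands the dark-vessel region until g stops it), at most
200 steps with early stop after 10 iterations of an unchanged zero set. The
final mask keeps the largest component(s) above the minimum area.

**Skeletonization** is canonical two-subiteration Zhang–Suen thinning
(neighbors P2…P9 clockwise from north): delete when the neighbor count B ∈
[2, 6], the cyclic 0→1 transition count A = 1, and the directional products
P2·P4·P6 = P4·P6·P8 = 0 (subiteration 1) or P2·P4·P8 = P2·P6·P8 = 0
(subiteration 2), until a full pass deletes nothing. Exact agreement with a
brute-force per-pixel reimplementation is tested on 50 random masks. Note
that on dense random blobs the algorithm can legitimately retain thick
junction knots; the single-pixel-width guarantee is asserted on tubular
masks, which is the domain it is used on. An optional spur pruner removes
side branches shorter than a threshold (off by default; whether short
branches should be pruned before width estimation is left to the operator).

**Edge detection** is Canny from its five classical steps: truncated
(±⌈3η⌉), renormalized Gaussian smoothing (η = 1.0); 3 × 3 Sobel gradients
with magnitude √(g_x²+g_y²) and quadrant-aware direction (two-argument
arctangent — the single-argument form loses the sign); non-maximum
suppression along the direction quantized to 0°/45°/90°/135° with ties
retained under ≥; double thresholding at 0.1/0.2 of the peak magnitude
(relative by default, absolute available); and hysteresis keeping weak
pixels 8-connected to a strong one.

**Edge source for the width estimator.** By default the pipeline feeds RETC
the segmentation-mask boundary at the outside offset rather than the raw
Canny map (`edge_source="mask"` vs `"image"`). The reason is geometric: for
a symmetrically blurred band the discrete gradient peak lies exactly between
the last lumen pixel and the first background pixel. On noiseless images a
small asymmetry from the two edges' overlap breaks the tie toward the
outside pixel and Canny recovers the width exactly, but under realistic
noise the tie breaks at random per column, scattering edges one pixel inward
and biasing D low. The mask boundary, produced by the level set whose Otsu
initialization crosses at the true boundary, is stable under noise and
matches the d = 2r − 1 calibration by construction.

## Manual reference and evaluation statistics

The reference width at an operator-chosen vessel point is measured by a
rotating ruler: the foreground chord length through the anchor is read at
0°, 20°, …, 160° (nine angles, counterclockwise from the image-horizontal
axis) and the minimum is the reference width — the shortest chord crosses
the vessel perpendicular to its axis. Readings sample the line every
0.25 px with nearest-pixel lookup and report (number of foreground samples)
× 0.25, which equals the pixel count of an axis-aligned band and grants the
sub-pixel readings a manual ruler tool produces. Two discretization facts
matter: the nine angles straddle the true perpendicular by up to 10°, so a
band of width w reads up to w/sin(80°) ≈ 1.015 w; and oblique chords of a
discrete shape quantize up to half a pixel short per end.

Estimates are scored against references by e_i = |w̄_i − w|, their mean μ_e,
and their **population** variance δ_e (divisor n, exactly as the statistic
is defined), plus a per-image relative accuracy 1 − e/w rounded to two
decimals. The accuracy formula is a reconstruction — its defining check is
that it reproduces all ten published accuracy cells from the published
(estimate, reference) pairs, which the test suite verifies.

## Synthetic phantoms

The generator emulates the target imaging: dark vessels (intensity 60) on
bright tissue (180) in a 100 × 100 frame, with straight, sinusoidal
(amplitude 6 px, period 70 px — the gentle curvature of superficial forearm
veins at this resolution) and bifurcating (30° branch) centerlines, constant
or linearly tapered widths (odd defaults, so the one-pixel centerline is
symmetric; even widths are inherently ±0.5 px ambiguous). Vessels run
border to border like a vein crossing the field of view. The mask contains
exactly the pixels within width/2 of the continuous centerline; the
rasterized centerline takes one pixel per unit arc step so every centerline
pixel is within 0.5 px of the curve — this is what makes the exact-recovery
identity (D = w with outside edges) hold on curved vessels too.
Degradation adds Gaussian blur, seeded additive Gaussian noise, and a linear
illumination ramp, leaving the ground truth untouched.

What the phantoms do **not** emulate: tissue texture, vessel intensity
profiles (real veins have smooth Gaussian-like cross-sections, not flat
cores), depth-dependent contrast, specular artifacts, and multi-vessel
scenes beyond one bifurcation. Passing the phantom suite therefore
demonstrates the geometric correctness of the estimator and the pipeline's
robustness to blur/noise/illumination at the stated levels, not clinical
accuracy on patient images.

## Problem sizes and numerical choices

Tests run on 100 × 100 phantoms (the nominal frame size of the target
imaging), 32 × 32 masks for thinning oracles, and 64 × 64 grids for the
RETC equivalence fixtures; the level set runs at most 200 iterations.
Integer conversions round half up; neighborhood filters replicate edges;
the level-set gradient guard is 1e-10; non-maximum-suppressed magnitudes
below 1e-6 are treated as zero so float residue on flat images cannot seed
relative thresholds. Ties in NMS are retained (≥) and resolved by the
thresholds. Degenerate inputs fail loudly and specifically: constant images
cannot be cropped automatically or segmented ("no vessel candidate found"),
empty masks cannot be thinned, an all-excluded width profile is an error.

## Known limitations

- Widths are pixel-quantized; no sub-pixel radius refinement is attempted,
  so individual d_i carry ±1 px error by construction (the segment mean is
  much tighter).
- The balloon weight α is fixed; very low-contrast vessels may under- or
  over-segment, shifting the mask boundary and hence D by up to a pixel.
- The learned first-stage enhancer is a hook only; no trained model ships.
- Bifurcation points contribute skeleton pixels whose tangent circle touches
  the nearer branch edge; per-branch widths are out of scope.
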