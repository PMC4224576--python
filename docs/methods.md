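# Methods

This note records the model behind each pipeline stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## The image representation

A bilayer frame is reduced to one lateral marker point per molecule: the PO4
phosphate bead for DPPC and DUPC, the ROH hydroxyl bead for cholesterol, and
the equal-weight centre of mass over all beads for a protein. Markers are
wrapped into the periodic box and binned onto a grid of 1 × 1 Å pixels
(pixel (i, j) covers the half-open square [i, i+1) × [j, j+1) Å; grid
dimensions are the box edges rounded to the nearest Å, re-derived per frame
because the barostat makes the box fluctuate). Bins hold *counts* rather
than 0/1 flags, so two markers sharing a pixel are not silently merged; at
~53 Å² per lipid this almost never differs from a binary indicator.

Equal weights for the protein centre of mass are deliberate: bead masses are
not read from any topology, and only the lateral position at ~20 Å
resolution is consumed downstream.

All analysis operates leaflet by leaflet. Leaflets are assigned against a
flat midplane at the mean z of all phosphate markers; each lipid follows its
own marker's side. This presumes a non-undulating bilayer — the entire 2D
representation does — so frames where more than 5 % of markers lie within
5 Å of the midplane are rejected with an explanatory error rather than
analysed wrongly.

## Density fields

Count grids are convolved with a periodic Gaussian normalised to unit sum
over the grid, so the field integral always equals the marker count (exact
mass conservation). The convolution is circular (FFT) with a minimum-image
kernel; wrap-around handling is physical here, since the simulation cell is
periodic and zero padding would manufacture interfaces at the box edge.

The lipid smoothing width interprets "each lipid takes equal space": the
Gaussian σ is the radius of a circle of area A/n, σ = √(A/(nπ)) — 4.1 Å for
3000 lipids in a 400 Å square leaflet, and derived per frame from the
frame's own count and box unless overridden. "Width" is read as the
standard deviation, the default meaning of the smoothing parameter in the
standard image filters; this is stated prominently because the alternative
(FWHM) reading would change every downstream number. The protein footprint
uses σ = 20 Å, half the ~40 Å centre-of-mass distance of two interacting
proteins; it is unit-normalised for consistency (only fractions under the
footprint are consumed, so normalisation cancels).

## Phase masks

Ld is every pixel where the DUPC − DPPC density difference strictly exceeds
the mean of that difference field, per leaflet per frame; ties are Lo.
Cholesterol never enters the mask definition. The per-frame mean threshold
is parameter-free, but two consequences are worth knowing:

* the threshold sits at the area-weighted mean of the two phases' density
  levels, not at their midpoint, so the measured boundary shifts ~2 Å into
  the majority phase and the minority-phase area is slightly inflated;
* when the phase areas are very unbalanced (minority below ~15 % of the
  box), the mean approaches the majority level and density noise crosses it
  freely — mean-threshold masks of strongly asymmetric mixtures are
  speckled by construction. Analyses here keep minority fractions ≥ 20 %.

## Interface detection and length

The Canny stages are implemented explicitly with periodic boundary handling
throughout: Gaussian-derivative gradients at σ = 2 Å (`wrap` mode),
non-maximum suppression along the bilinearly interpolated gradient
direction, and hysteresis at 0.1 / 0.2 of the maximum gradient magnitude
with periodically merged components. Two choices are deliberate:

* NMS uses an asymmetric tie-break (≥ forward, > backward) plus a
  single-response cleanup along the rounded gradient direction, so a
  symmetric step — a mask boundary lying exactly between two pixel columns —
  yields exactly one edge chain, not two. Off-the-shelf detectors keep both
  tied pixels, doubling the measured length of axis-aligned interfaces.
* Hysteresis thresholds are relative to the gradient maximum because the
  gradient of a smoothed unit step at σ = 2 peaks near 0.2, and absolute
  thresholds at that scale would be arbitrary.

Interface length is the edge-pixel count × 1 Å. This estimator is exact for
axis-aligned boundaries and biased for diagonal ones (measured: circles
+4…6 %, an exact 45° boundary is the worst case); an optional chain
estimator weighting diagonal adjacencies by √2 is provided but non-default.
Domains are 8-connected components (4-connectivity fragments diagonal necks
that are visually single domains), merged across both periodic seams by
union-find, with periodic-aware centroids (circular mean) and equivalent
radius √(area/π). The mean domain radius is an unweighted mean over domains
with area ≥ 100 Å² (suppressing small islands; the cutoff is exposed). A
`phases` argument restricts which phases contribute, because in a
circular-domain geometry the percolating background sea would otherwise
dominate the mean; the default uses both phases.

## Leaflet coupling and species partition

Overlaying the two leaflets' masks classifies each pixel both-Lo, both-Ld
or mismatch; the three fractions sum to 1 and the mismatch fraction is the
registration metric tracked over time. Two independently mixed leaflets sit
near 2·p(1−p) ≈ 50 % mismatch and coupled phase-separated bilayers fall far
below — the pipeline measures ≈ 49–50 % on freshly mixed synthetic frames.
The fraction of a species' density lying in Ld (e.g. cholesterol, expected
mostly Lo) is the mask-restricted density sum over the total.

## Thickness

Leaflet surfaces are built by cubic (Clough–Tocher) interpolation of the
phosphate z-coordinates onto pixel centres — phosphate-to-phosphate is the
thickness convention, and cholesterol ROH beads are excluded. Scattered-data
interpolators are not natively periodic, so markers within 25 Å of a box
edge are tiled with their periodic images before fitting and only the
central tile is evaluated. Markers sharing a pixel cell are merged (z
averaged) first: near-coincident support points with different z make the
triangulation ill-conditioned and the cubic interpolant spike. Degenerate
point sets fall back to linear interpolation with a warning; pixels outside
the convex hull (none, in periodic use) are filled nearest-neighbour.

Thickness is upper minus lower surface per pixel. Non-positive pixels are
unphysical for a bilayer; they are counted, logged, and excluded from
statistics. Per-category statistics (both-Lo / both-Ld / mismatch / global)
use 0.5 Å histogram bins on a shared range; because all statistics run over
the same retained pixels, the identity *global mean = Σ category fraction ×
category mean* holds to machine precision and is asserted in tests.

## Protein classification

f_Ld is the footprint-weighted average of the binary mask of the protein's
own leaflet — a literal "proportion of each phase under the Gaussian", not
a hard 20 Å disc, and mask-based rather than density-based (the continuous
difference field is the documented alternative). Labels use strict
inequalities: Lo if f_Lo > 0.8, Ld if f_Ld > 0.8, otherwise interfacial —
exactly 80 % is interfacial. Protein beads are excluded from the lipid
density fields, so the mask under a protein is whatever the surrounding
lipids imply.

## Kinetics

Interface length and mean domain radius both serve as the characteristic
length L(t); fits are unweighted least squares on (log t, log L) over a
user-supplied window. Regime boundaries are not auto-detected — with ≲ 10
frames per decade, automatic change-point detection would overfit noise.
Condition comparisons report per-time means and min–max envelopes with
nearest-frame matching; no value is carried across a gap larger than one
median frame interval, and interpolation across frames is never done.

## The synthetic generator

The generator's purpose is exact ground truth, and its defaults are the
reference system: a 5 : 3 : 2 DPPC : DUPC : CHOL composition (751/450/299
per 1500 lipids, scaled by largest-remainder rounding — ×4 gives the
6000-lipid patch whose solvated bead total, 137 232, the bookkeeping
helper reproduces), ~400 Å square boxes at ~53 Å² per lipid, blue-noise
marker placement with 5 Å minimum distance (liquids have short-range order;
lattices would alias at 1 Å pixels), leaflet separations of 45 Å (Lo),
36 Å (Ld) and 41 Å (mixed) with 1 Å z-jitter, and a 3 Å mixing band at
planted interfaces so the compositional step is not unphysically sharp.

Two emulation choices matter for interpreting test results:

* **Phase-separated frames carry no compositional shot noise.** Each species
  is placed as its own blue-noise pattern inside its phase region (DUPC in
  Ld; DPPC and cholesterol independently in Lo, at 0.75 of their mean
  spacing). A real MD frame mixes species randomly within a phase, which
  puts ~1–2σ of density noise against the mean threshold and speckles the
  mask — so passing recovery tests here demonstrates the correctness of the
  measurement chain on clean geometry, not robustness to compositional
  fluctuations. The randomly *mixed* generator keeps full label randomness
  (one point set, random species permutation), which is why the ~50 %
  mismatch measurement is a genuine noise-regime test.
* **Coarsening series use circular domains, not stripes.** The imposed
  L(t) = r₀(t/t₀)^α is carried by the circle radius, which is continuous;
  stripe counts are integers and quantise L(t) too coarsely for exponent
  recovery at ten frames. The domain count tracks a target Ld area fraction
  (0.3), and circles keep 12 Å gaps so neighbouring domains remain
  resolvable after 4 Å smoothing. Measured radii carry a ~+2 Å bias
  (threshold shift + pixelation), which flattens fitted exponents by a few
  hundredths — the recovery tolerance (±0.05) sits above this bias, not
  above zero.

Other realities the generator does not emulate: lipid dynamics or energetics
(frames are independent draws, not a trajectory), undulations, curvature,
protein–lipid interactions (planted proteins are points with labels), and
area-per-lipid differences between phases (density is uniform across phases
by default).

## Problem sizes

Default test and example sizes are one 400 Å frame (3000 lipids/leaflet) for
recovery checks, 200 Å boxes (~750 lipids/leaflet) for the ten-frame
coarsening series, and ten 400 Å frames for the mismatch average — sizes at
which every quantity here is statistically stable while a full run stays in
the minutes range on one CPU.

## Known limitations

* The mean-threshold mask degrades for strongly asymmetric phase areas (see
  above); a fixed or Otsu threshold would behave differently and is not
  implemented.
* The pixel-sum interface length is diagonal-biased by design; comparisons
  across frames are fine (the bias is geometry-stationary), absolute lengths
  of strongly diagonal interfaces are a few percent high.
* Leaflet assignment fails on undulating bilayers by construction, and no
  curvature correction is attempted.
* GRO is the only trajectory format read natively (single- and multi-frame);
  other formats should be converted first.
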