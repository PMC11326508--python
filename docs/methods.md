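# Methods

`spinedet` implements the computational core of a heatmap-based vertebra
landmark detector for scoliosis assessment: the label codec that turns
17-vertebra corner annotations into dense supervision tensors and back,
the auxiliary inter-vertebral targets, the sparse-to-dense vertebral
line interpolation, the composite training loss, Cobb angle estimation,
and the detection metric suite.  Everything is exercised end-to-end on a
parametric synthetic spine generator, so no clinical data are required
to run or test the package.

## The detection model

An anterior-posterior spinal radiograph is annotated with 17 vertebrae
(12 thoracic + 5 lumbar), each by its 4 body corners, 68 landmarks in
total.  Detection follows the center-point paradigm: a convolutional
encoder-decoder predicts, on a grid downsampled by `k` (default 4),

1. a **center heatmap** — one unnormalised 2-D Gaussian disc per
   vertebra centroid, peak 1 at the quantised center pixel, overlapping
   discs merged by maximum;
2. a **center offset** field — the fractional remainder
   `(x/k − ⌊x/k⌋, y/k − ⌊y/k⌋)` lost to quantisation;
3. **polar corner offsets** — each corner written as `(r, θ)` about its
   center, with the polar axis along +x and θ measured toward +y (the
   image frame is y-down); decoding applies
   `x = x_ct + r·cosθ, y = y_ct + r·sinθ`.  The Cartesian system is kept
   for center localisation, the polar one for corners, where the
   near-symmetric vertebra shape makes radii and angles the natural
   variables;
4. **CPIE** (center point interval estimator) — the vector from each
   center to its inferior neighbour, anchored at the superior vertebra's
   center pixel;
5. **AVIE** (adjacent vertebra interval estimator) — the offsets from a
   vertebra's two bottom corners to the next vertebra's two top corners,
   anchored at the inferior vertebra.  Both interval targets inject the
   between-vertebra geometry that single-point supervision ignores, and
   matter most where soft-tissue interference is strongest (the lower
   spine);
6. **vertebral lines** — dense equidistant samples of smooth curves
   through the left corners, the centroids, and the right corners
   (sparse-to-dense label densification).

Inference runs 3×3 non-maximum suppression on the heatmap, takes either
the top-17 peaks (fixed k) or every peak above an intensity threshold of
0.05 (adaptive), restores sub-pixel centers with the offset field, and
converts the polar corner channels back to 68 Cartesian landmarks.

All offsets and radii are stored in full-resolution pixels at the
reference vertebra's quantised center pixel.  With that convention,
encode→decode is an exact inverse up to floating point as long as no two
centers share a grid pixel; the test suite verifies a ≤1e-6 px round
trip over 200 random synthetic spines.

### Gaussian width

The disc width is not a free-standing constant: by default the radius is
derived per vertebra from its bounding box on the grid as the largest
displacement that keeps box IoU ≥ 0.7 (the keypoint-detection lineage
convention), with σ = radius/3 and the radius floored at one grid cell.
A fixed-σ override exists (`CodecConfig(sigma_policy=("fixed", s))`).

## Vertebral line interpolation

Each enabled line interpolates its control points (34 corners for
left/right, 17 centroids for middle) with a cubic B-spline,
chord-length parameterised — the defining requirement is that every
control point lies on the curve, which `scipy.interpolate.make_interp_spline`
guarantees.  Arc length is tabulated over 10,000 piecewise-linear
subdivisions and inverted by linear interpolation to place 100 samples
(endpoints included) at equal arc spacing.  Equidistance is validated
against independent Gauss–Kronrod quadrature of the spline speed
(< 1% relative spread) and against the closed-form quarter-circle
spacing (< 0.5% error).  Only the middle line is enabled by default; the
left/right lines cost two extra regression heads for little measured
benefit at full scale.

## Loss composition

`L = α1·L_hm + α2·L_center + α3·L_corner + α4·L_CPIE + α5·L_AVIE + α6·L_VIL`
with α1..α5 = 1 and α6 = 0.05 (the line term sums over 100 dense points
and is scaled to keep terms of similar size).  `L_hm` is the
penalty-reduced focal loss (exponents 2 and 4, normalised by the number
of peak pixels); all regression terms are masked L1 over supervised
pixels only; `L_VIL = L_vil_l + L_vil_m + L_vil_r` with disabled lines
contributing zero.

One deliberate deviation: the angular channels of the corner loss use a
wrapped L1, `min(|Δθ| mod 2π, 2π − |Δθ| mod 2π)`.  A plain L1 on θ is
discontinuous at the ±π branch cut (a corner sitting near the cut would
incur a spurious ~2π error), and during training an unbounded θ head
combined with the naive `min(d, 2π−d)` form is actually unbounded
below.  The training loop wraps by subtracting the nearest whole number
of turns (a stop-gradient shift), which is identical in value and gives
the correct sub-gradient.

## Cobb angles

Per vertebra, the slope vector runs from the left-edge midpoint (mean of
the top-left and bottom-left corners) to the right-edge midpoint.  The
17×17 matrix of pairwise angles is `arccos` of normalised dot products,
clipped to [0°, 90°].  MT is the global maximum, attained between
vertebrae p1 < p2.  For a C-shaped spine, PT is the angle between the
first vertebra and p1, TL between the last vertebra and p2; for an
S-shaped spine (detected by a sign test of the endplate midpoints'
lateral residuals about the chord from first to last midpoint), PT and
TL are instead the sub-range maxima above p1 and below p2.  The S-curve
handling follows the measurement convention of the scoliosis-challenge
reference tooling and can be disabled (`s_curve_handling=False`).  The construction is invariant to
translation, rigid rotation, and uniform scaling of the landmark set.

Caveat: with angles clipped to [0°, 90°], near-parallel pairs make the
`arccos` ill-conditioned (√ε-level noise, ~1e-7 degrees); invariance
tests therefore use spines whose three angles are all away from zero.

## Metrics

* **MDE** — mean Euclidean distance in pixels over index-aligned
  landmarks; poolable over a dataset (the mean runs over every landmark)
  and splittable into the upper-10 / lower-7 vertebra regions that
  differ in background interference.
* **SMAPE** — per case, the summed absolute angle errors over the summed
  (pred + gt) angles across PT/MT/TL, case-averaged, ×100 (percent
  scale); per-angle variants restrict to one angle.  Symmetric in
  prediction and ground truth.
* **Self-adaptive MDE** — decodes centers adaptively (threshold 0.05, so
  the count may differ from 17), matches predicted to true vertebrae by
  minimum-total center distance (Hungarian algorithm via
  `scipy.optimize.linear_sum_assignment`; surplus predictions stay
  unmatched), and averages the corner error over matched vertebrae only.
  This separates localisation error from vertebra-ordering error; the
  matching cost is center-to-center distance (the whole-landmark-set
  mean distance is available as an alternative through
  `hungarian_match` on stacked landmarks).

## Synthetic spine generator

The generator defines the study conditions for every test.  A centerline
`x(t) = W/2 + Σ A_k sin(2π f_k t + φ_k)`, `y(t)` linear from a 60 px top
margin to its mirror, carries 17 rectangles rotated to the local
tangent.  Per case, amplitudes are drawn uniformly from [0.3, 1]×A_k and
phases from [0, 2π), so one parameter set spans a family of curvatures;
the default amplitude of 40 px at 1024×512 yields main-curve angles up
to roughly 25°, and the two-sinusoid recovery setting (60 px + 25 px at
1 and 2 cycles) reaches ~40° with frequent S-shapes.  Vertebra width
(80→120 px) and height (34→44 px) grow linearly down the spine as the
anatomy does; centers follow arc spacing of (1 + gap_fraction)×height
with gap_fraction 0.25.  Because the tangent is closed-form, the true
Cobb triple is computed analytically from the tangent normals — not
from the emitted corners — through the same partition rule as the
landmark-based estimator, making parameter recovery a meaningful
dual-route check (it agrees to ~1e-6°; the 1° test tolerance covers the
construction, not numerical slack).

Rendering fills the quadrilaterals bright over a dark background, blurs
edges (σ = 1.5 px), adds a low-pass clutter texture whose amplitude
ramps linearly from zero at the top row to `lower_region_clutter` at the
bottom (emulating the heavier abdominal-tissue interference over the
lower spine), and adds Gaussian intensity noise (sd 0.03 on the [0,1]
scale), quantised to 8-bit PNG-compatible images.

What the generator does **not** emulate: ribs, pelvis and cervical
anatomy, exposure inhomogeneity, more-than-17 visible vertebrae, and
annotation jitter.  Passing tests therefore demonstrate the
correctness of the codec, geometry and metrics, and that the training
signal exists end-to-end — not clinical-grade performance on real
radiographs.

## The toy network

The package trains its network with a small reverse-mode autodiff core
written on numpy (`spinedet.autodiff`; gradients are finite-difference
checked).  The toy preset is a U-shaped stack of single-conv blocks
(widths 12/24/32/48, strides 1/2/2/2) with one upsample+skip decoder
block (width 32), per-pathway 3×3 heads, and a global-average-pool +
linear head for the vertebral line coordinates (squashed to [0,1]
image-normalised units) — about 58k parameters.  Two coordinate
channels are appended to the input (CoordConv-style): the grid heads
supervise a handful of absolute positions per image, which a purely
translation-equivariant network cannot express.  A `resnet34-like`
preset exposes the full-scale widths (five encoder blocks 64–512, three
decoder blocks) for shape-contract purposes; training it is out of
scope.

Training is full-batch Adam (β = 0.9/0.999).  The toy preset uses a
learning rate of 5e-3 — appropriate for a 58k-parameter network
memorising two cases — while the `resnet34-like` preset carries the
full-scale recipe default of 1.25e-4.  The overfit demonstration runs
500 steps on two simulated 192×96 cases; that scale keeps adjacent
vertebra centers ≥ 2 grid cells apart (the 3×3 suppression window
cannot resolve 17 peaks below that) and the decoded mean landmark error
reaches ~1–3 px against a 4 px grid cell.

## Numerical choices and edge cases

* Top-k peak selection breaks value ties by row-major pixel index; the
  adaptive threshold comparison is strict (`> 0.05`).
* A corner coincident with its center encodes as (r=0, θ=0).
* Spline degree drops automatically when fewer than degree+1 control
  points are given; duplicate consecutive control points are an error.
* Focal-loss predictions are clamped to [1e-7, 1−1e-7].
* A degenerate vertebra (zero-length slope vector) makes the Cobb
  computation fail loudly rather than return arbitrary angles.
* Problem sizes in the checks: 200 spines for the round trip, 100 for
  Cobb recovery, 100 brute-force matching instances (n ≤ 7), 10 spines
  × 3 lines for quadrature-checked equidistance, 500 training steps on
  2 cases for the overfit demonstration.

## Known limitations

* The Cobb regional partition (PT/TL selection) follows one published
  convention; clinical software varies in how it picks the secondary
  curves, and angles are capped at 90°.
* The renderer is a statistical stand-in, not an X-ray physics model;
  detector performance numbers on it do not transfer to real scans.
* The toy network demonstrates the learning signal, not accuracy at
  clinical resolution.
* MAT-file support covers the 68×2 landmark-array convention only.
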