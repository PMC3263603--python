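# Methods

## The detection model

`pelvifrac` treats fracture detection as a local topology question on
the segmented bone boundary. An unbroken bone shows, inside a small
window centered on its boundary, exactly one continuous edge curve; a
fracture interrupts that curve, so the window contains two or more
separate edge components. The chain therefore (i) finds bones and puts
landmarks on their boundaries, (ii) cuts a size-adaptive window around
every landmark, (iii) refines the window's edges with an undecimated
wavelet transform, (iv) isolates the bone contour with Otsu masking,
and (v) counts traced 8-connected boundaries. The per-window rule is
deliberately simple: `fractured = (boundary_count > 1)`; an empty
window is "not fractured" and flagged separately.

Assumptions: a single 2D axial slice; bone appears brighter than soft
tissue, soft tissue brighter than air; one fracture appears as a dark
gap separating bone into pieces within at least one window; bones of
interest are large relative to the image noise scale. No 3D context,
no Hounsfield calibration, no fracture-type classification or
displacement measurement.

## Stage conventions and parameters

All intensities are floats in [0, 1] (8/16-bit PNG/TIFF and DICOM
rescaled at the I/O boundary; DICOM slices are min–max normalized
after slope/intercept). Pixels are indexed 0-based as (row, col).
Every parameter below lives in `PipelineConfig`, is overridable from a
flat `key = value` file, and is hashed into every report.

**Conditioning.** Blob analysis thresholds the slice at the lowest cut
of a 3-class multi-Otsu split (CT slices are roughly trimodal:
air / soft tissue / bone; plain 2-class Otsu lands *between* tissue
and bone and would discard the body). The largest 8-connected
component, holes filled, is the body; everything outside is set to 0.
Denoising is a Gaussian with `gaussian_sigma` = 1 px (replicate
padding, mean-preserving). Contrast is stretched linearly between the
1st and 99th intensity percentiles, clipped. A Canny edge map with
removal of components shorter than 10 px is exposed for edge-based
consumers; the main chain works on the conditioned intensity image.

**Segmentation.** Bone = connected components of
`intensity >= bone_threshold` (default 0.6 after stretching), closed
with a disk of `bone_close_radius` = 12 px, hole-filled, and kept when
the filled area is at least `min_bone_area` = 300 px². The closing
makes a region describe the *whole* bone: a fracture gap up to twice
the radius does not split the bone into separate regions, so — like a
shape-model segmenter fitting the overall bone outline — the boundary
passes across the gap and the window size is set by the whole bone's
area. Distinct bones must lie further apart than twice the radius.
The outer boundary is traced with the Moore neighborhood (Jacob's
stopping criterion), oriented counter-clockwise in display
coordinates, starting at the topmost-then-leftmost pixel.
`n_landmarks` = 50 points are sampled at equal arc length along the
boundary, landmark 0 at the start pixel. The default of 50 gives
window strides comparable to the window side for phantom-scale bones.

**Windows.** Window area `W = A/6` with the empirical constant 6; the
side is `S = nearest_odd(sqrt(A/6))` (ties to the smaller odd value),
forced odd so the landmark is an exact center pixel, clamped to 3 and
flagged when `sqrt(A/6) < 3`. Crops are replicate-padded at image
borders (zero padding would create fake edges) and rescaled to 256×256
with bilinear interpolation, no renormalization. Note that nearest-odd
rounding can distort `S²/W` by more than 25% for areas below ≈ 480 px²
(e.g. A = 216 gives sqrt(A/6) = 6 exactly, equidistant between 5 and
7); from ≈ 480 px² upward the ratio stays within [0.8, 1.25].

**Stationary wavelet transform.** PyWavelets' `swt2` with the Haar
pair lo = [1, 1]/√2, hi = [−1, 1]/√2, applied as circular correlation
`y[n] = Σ_k f[k] x[(n+k) mod N]`; periodic extension makes the
transform exactly equivariant under circular shifts, which the tests
exploit. Orientation convention: cD^(h) responds to steps across
columns (vertical edges), cD^(v) to steps across rows. (PyWavelets
names the two slots the other way around and negates them; the wrapper
remaps.) Three decomposition levels by default (`swt_levels`,
1–4): level 3 suppresses noise well while keeping edges sharp, and
deeper levels add cost without filtering benefit. Reconstruction of
single-level detail arrays uses the closed-form Haar à-trous inverse
(two-tap synthesis per axis and level; exact, cross-checked against
`pywt.iswt2` and by the perfect-reconstruction identity
input = approx + Σ details to < 10⁻⁶ relative error).

**The chosen detail array.** The edge map fed to masking is the
combined level-3 magnitude of the *analysis coefficients*,
`M = |cD3^(h)| + |cD3^(v)| + |cD3^(d)|` (`detail_source =
"coefficients"`). The reconstructed detail arrays (also available,
`"reconstructed"`) are band-pass and therefore odd around an edge:
their magnitude is exactly zero on the edge centerline, which splits
the binarized ridge into two parallel strands and can double the
boundary count on perfectly intact edges — increasingly so at high
window zoom, where the valley widens. The analysis coefficients of a
(blurred) step are single-signed and peak at the edge, giving an
unbroken ridge. Both sources share the same support and scale.

**Masking.** Otsu's threshold is computed by an exhaustive scan over
256 uniform bins between array minimum and maximum; binarization
compares bin indices against the selected cut, so the result is
bit-reproducible and exactly invariant under positive rescaling. Ties
resolve to the smallest threshold; a single-occupied-bin histogram is
flagged degenerate. The returned statistics satisfy
σ_w²(t) + σ_b²(t) = σ² at the cut (asserted to 10⁻⁹ in the tests).
Before binarizing, M is smoothed with `detail_sigma` = 2 px (ridge
strength oscillates along oblique edges; the envelope keeps the ridge
contiguous) and its outer `mask_border` = 16 px frame is zeroed: with
periodic analysis, the wrap-around jump at the window frame is usually
the strongest "edge" in the window and would otherwise dominate the
Otsu split and trace as a fake boundary. The mask W_m Gaussian-smooths
the window (`mask_sigma` = 2 px), Otsu-binarizes it, keeps every
foreground piece above `mask_min_component_fraction` = 0.5% of the
window (*every* piece, not only the largest — the fragments on both
sides of a fracture must stay in the mask or the second boundary can
never be seen), fills holes, and forms the band within
`mask_dilation` = 5 px of each piece's contour. A band, rather than
the dilated blob, excludes the transform's interior side lobes while
keeping dual edges of minor fractures; the same border frame is
excluded. W_e = W_b × W_m is a pixelwise AND. A binary closing of
radius `mask_closing` = 2 px then bridges hairline breaks in W_e —
far below any fracture gap at window scale (a 6 px gap appears as
≥ 40 px after zooming).

**Tracing and aggregation.** Components below
`small_object_fraction` = 1% of the window area are removed (area
opening with strict inequality — 655.36 px on a 256×256 window, so a
655-px component is removed and a 656-px one kept; an opening with a
structuring element would also erode genuine thin edges). Each
remaining 8-connected component becomes one traced boundary: a
deterministic depth-first walk with clockwise Moore-neighbor priority
from the topmost-leftmost pixel, recording backtracking steps so
consecutive positions stay 8-adjacent and every pixel is covered.
`closed` is decided topologically (the component encloses interior
area). Within a bone, flagged windows are merged into maximal runs
over the circular landmark order; a run of at least `min_consecutive`
= 1 windows is a fracture site, any site marks the bone, any bone
marks the slice. The slice-level rule is the package's choice; the
evaluator accepts labels at any granularity.

**Evaluation.** accuracy = (TP+TN)/all, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), each ×100, counted at slice level.

## The phantom generator

`phantoms` renders what the chain needs to be exercised honestly:
bone-like cross-sections (ellipses perturbed by low-order harmonics,
mimicking iliac-wing outlines) with a bright cortical shell
(intensity ≈ 0.85–0.95) and slightly darker medullary interior
(−0.05), on a soft-tissue body ellipse (0.25) over air (0.0); additive
Gaussian noise (σ = 0.02, at least 3σ below the bone–tissue contrast)
applied after shape rendering, so the Gaussian denoising stage has
real work to do; and bright table-like bars outside the body. Fracture
gaps are straight fracture-plane cuts of controllable width (suite
default 6–14 px) along the chord perpendicular to the radial direction
at the gap angle, at 0.35 of the local outline radius: a fracture line
crosses the whole cross-section, so one gap fully severs bone and
cortical shell into two fragments, which is how gap-type fractures
present in axial slices. The standard suite draws two well-separated
bones per 384×384 slice (characteristic radii 45–56 and 26–34 px,
cortical thickness 5–8 px) and 1–2 gaps per fractured slice, all
randomness derived reproducibly from one seed (independent streams for
artifacts and noise, so ablating one leaves the other bit-identical).

What the phantom does **not** emulate — and what passing tests
therefore do not show about patient data: Hounsfield calibration and
scanner reconstruction kernels, partial-volume effects and intensity
inhomogeneity, textured trabecular bone interiors, soft-tissue organs
and vessels, hairline fractures without separation, impacted or
comminuted fractures, joint spaces between adjacent bones closer than
the segmentation's merge distance, and 3D continuity across slices.
Performance numbers on the phantom suite characterize the chain's
behavior under its stated assumptions, not clinical accuracy.

## Numerical choices and degenerate inputs

- Haar taps are 1/√2 each, so coefficient magnitudes are reproducible;
  all SWT algebra is exact to machine precision.
- Otsu binning: 256 uniform bins over [min, max]; thresholds reported
  as the lower edge of the first upper-class bin.
- Boundary tie-breaks: start pixel topmost-then-leftmost; clockwise
  Moore scan order (N, NE, E, SE, S, SW, W, NW) for walks; regions
  ordered by decreasing area; equal-area ties keep label order.
- Degenerate inputs: an all-flat image warns and passes through
  conditioning unchanged; no component above the bone threshold gives
  an empty region list (a valid "no bones" slice); a window whose
  cleaned edge image is empty is flagged `empty` and counted as not
  fractured; `sqrt(A/6) < 3` clamps the window side to 3 and flags the
  geometry.
- Problem sizes in the shipped checks: the end-to-end study uses
  50 fractured + 50 intact slices at 384×384 with 50 windows per bone,
  and a 9-point gap-width sweep (4–20 px); exactness checks use 50
  random histograms, 10 oracle images, and 100 random tracing images.
  These sizes make the full suite complete in a few minutes on one CPU
  while keeping every stage exercised at its native 256×256 window
  resolution.

## Known limitations

- The boundary-count rule cannot distinguish a second *bone* entering
  a window from a second *fragment*; bones closer together than about
  one window diagonal would need the landmark sidecar route or
  per-bone masking.
- A fracture gap wider than twice `bone_close_radius` splits the bone
  into separate regions; each fragment is then analyzed alone, and
  windows sized by fragment area may no longer span the gap. Widely
  displaced fractures are better served by increasing
  `bone_close_radius`.
- Otsu masking assumes a bimodal window (bone vs. background); windows
  fully inside bone or fully in soft tissue produce unstable masks and
  rely on the empty-window flag and the 1% filter.
- The per-window verdict is binary; no severity, displacement or
  angle measurement is attempted.
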