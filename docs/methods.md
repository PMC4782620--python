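# Methods

## Detection model

The detector treats a mammogram as a low-contrast smooth background plus
three kinds of bright structure: compact sub-millimetre spots
(microcalcifications), thin curvilinear ridges (mammary glands, vessels),
and large-scale tissue. It separates them by *size and shape* alone, in
four stages, with no learned components.

**Top-hat enhancement.** Grayscale opening with a flat structuring
element (SE) removes every bright structure the SE does not fit inside.
The enhancement image is

    E = f − max_i (f ∘ b_i),   i = 1…8,

the pixelwise maximum of openings by eight digital-line SEs at angles
k·180°/8 in a common 15 × 15 footprint (0.75 mm at the default
0.05 mm/pixel spacing). E equals, pixelwise, the *minimum* of the eight
individual top-hats: a structure is enhanced only if no line of the bank
fits inside it. Consequently the smooth background and any structure
spanning the footprint in some direction vanish, compact spots survive at
full contrast, and — deliberately — thin elongated ridges *also* survive
wherever their local tangent falls between the eight sampled
orientations or their curvature exceeds what a 15-px chord tolerates.
Those surviving ridges are handed to the next stage.

Line SEs are rasterized symmetrically: the direction vector is scaled so
its major component is 1, each half of the line is the rounded multiples
of that vector, and the second half is the point reflection of the first.
Every SE therefore contains its anchor, is point-symmetric, and has
exactly `footprint_px` pixels.

**Border policy for the morphology.** The input is extended once, by the
full SE extent, with a configurable rule (`reflect` default, `replicate`,
`constant(c)`), and both the erosion and the dilation run on that
extension before cropping. Padding the *eroded* image a second time
instead would violate anti-extensivity (opening exceeding the input) at
borders. A fourth policy, `clip`, restricts each min/max window to the
image domain (erosion sees +∞ outside, dilation −∞). `clip` forms an
adjunction on the image domain and is therefore *exactly* idempotent for
every SE; the extension policies are exactly idempotent in the interior
but not at borders for oblique SEs, because reflection maps a 22.5° line
to a 157.5° line, so extension and opening do not commute. The default
stays `reflect` because it avoids the spurious edge responses a constant
pad would create in the top-hat.

**Wavelet subband zeroing.** A 4-level separable DWT (symlet-2,
symmetric signal extension) decomposes E; the finest detail triplet and
the coarsest approximation are set to zero; the inverse transform is
cropped to the original shape and left signed (no clipping — the
segmentation threshold owns the semantics). Detail levels are numbered
1 = coarsest … n = finest, and the selector is fully configurable
(`SubbandSelector`). The premise is a scale gap: gland/vessel ridges are
roughly half the size of a detectable microcalcification, so their energy
concentrates in the finest (half-resolution) subbands while spot energy
sits one to two octaves lower.

Measured transfer of the default denoiser (peak out / peak in,
128 × 128 frames): a thin ridge (σ ≈ 0.5 px across) passes at ~0.31 when
axis-aligned but ~0.81–0.91 at oblique angles — a separable transform has
weak orientation selectivity away from 0°/90°. Compact blobs at
σ = 1–2 px pass at ~0.50–0.65. The wavelet stage therefore provides
strong suppression of fine *axis-aligned* structure and of the smooth
residual background, but oblique curvilinear residue survives and is the
dominant false-positive source — consistent with the known failure mode
of this detector family, where most false clusters arise from
interlacing linear tissue. The remaining stages absorb it.

**Segmentation.** Threshold the band-pass image and label 8-connected
components. The default method is the 0.999 quantile with an absolute
contrast floor of 0.13 (working scale): a per-image quantile adapts to
busy images but *always* marks 0.1 % of pixels, so a cluster-free image
would hallucinate candidates; the floor sets the minimal band-pass
contrast accepted as a candidate. A 3-px minimum component size then
discards ridge shards (threshold-crossing fragments of curvilinear
residue, typically 1–2 px) while spot responses at the retained scales
cover ≥ 3 px. Fixed and Otsu thresholds are available; Otsu on a
constant image degenerates to an empty mask with a warning.

**Cluster rule.** Candidate centroids are counted in square blocks of
`block_mm` = 10 mm (200 px at 0.05 mm/pixel; `block_px` is recomputed
from the spacing so the physical rule is preserved) anchored every half
block, the final anchor clamped to the image edge so every pixel is
covered. A block with ≥ 4 candidates (the operational definition of a
cluster: "four or more within 10 × 10 mm²") is a hit; hits sharing at
least one candidate merge transitively into one detection (union of
member sets and boxes). Membership is by centroid in the half-open block
box — unambiguous at block boundaries — and a tight cluster always lies
wholly inside at least one block of the half-overlapping grid.

## Phantom generator

`mcdetect.phantom` emulates exactly the structures the detector
distinguishes, not mammographic anatomy at large:

* **Background**: a Gaussian-smoothed random field (correlation
  ~150 px), rescaled to a ±0.08 band around base level 0.35 — smooth
  enough to vanish in the top-hat.
* **Spots**: isotropic Gaussian profiles truncated at 3σ, diameter
  defined as the truncated footprint (σ = diameter/6). Cluster defaults:
  4–10 spots, diameters 0.3–0.6 mm, amplitudes 0.2–0.35, centres drawn
  uniformly from a disc of radius extent/4 (2.5 mm) — a compact cluster
  within the 10 mm definition, and at roughly *twice* the ridge scale,
  which is the regime the method is designed for. A square-spot option
  supports exact-arithmetic tests.
* **Ridges** (gland/vessel confounders): cubic splines through random
  way-points, Gaussian cross-section of width 1–2 px (well under the SE
  footprint, so the top-hat passes them and the wavelet stage must deal
  with them), amplitudes 0.12–0.22 — deliberately overlapping the spot
  amplitude range, since amplitude is *not* the intended discriminant —
  with ±30 % multiplicative intensity jitter correlated at the
  ridge-width scale (gland-scale nonhomogeneity; correlating it at spot
  scale would make ridges locally indistinguishable from clusters and
  contradict the scale premise above).
* **Noise**: additive Gaussian, σ = 0.005.

Each layer draws from its own stream spawned from the master seed, so
layers vary independently. The default benchmark suite holds the
detector to a screening-like mix: 30 images of 1024² px (51.2 mm side),
~10 % containing one or two clusters, every image containing 2–6 ridge
confounders.

What phantoms do **not** model: breast-region boundary and pectoral
muscle, anatomic texture (the real background is structured tissue, not
a smoothed random field), benign macro-calcifications, scanner artifacts,
and the intensity statistics of any particular detector. Passing the
phantom benchmark therefore demonstrates the *mechanism* — scale-based
separation of spots from ridges and correct cluster logic — not clinical
performance; the published clinical figures of this detector family are
not reproducible without the private data they were measured on.

## Calibration of the operating point

The enhancement, wavelet, and cluster parameters are the published
configuration (8 SEs / 15 px, sym2 × 4 levels, 10 mm blocks, count ≥ 4).
The segmentation threshold has no published value, so it is the one
genuinely free parameter. It was calibrated by sweeping the contrast
floor (0.08–0.16) and minimum size (0–5 px) over 30-image validation
suites (seeds 1–5) and reading off the plateau where cluster sensitivity
stays at 100 % while false positives fall: floor 0.13, min size 3 px.
Held-out suites (five further seeds) confirm TPR 100 % with 0.07–0.20
false clusters/image. Both knobs remain configurable, and lowering the
floor toward 0.10 trades false positives for sensitivity to fainter or
smaller spots.

## Numerical and degenerate-input choices

* Working scale: float64 in [0, 1]; integer images are divided by their
  dtype maximum on read (monotone, bit-depth independent).
* Coordinates: row-major 0-based (row, col), origin top-left; all boxes
  half-open `[r0, r1) × [c0, c1)`.
* Morphology is computed by composition of scipy grey erosion/dilation
  on the pre-extended array and is exactly equal (no float tolerance) to
  the naive sliding-window definition; all operators are pure selections,
  so tests compare with `==`, not `allclose`.
* Wavelet reconstruction is cropped to the recorded original shape; odd
  sides are handled by the transform's standard extension bookkeeping.
  Perfect reconstruction holds to < 1e−8 (measured ~1e−12).
* Otsu on a constant image: empty mask + warning. Quantile threshold on
  a constant image: empty mask (strict `>` comparison).
* Component labels are deterministic: raster-scan order of each region's
  first pixel, contiguous from 1; min-size filtering relabels.
* Images smaller than one block: the block is clamped to the image so
  the pipeline still runs (the physical 10 mm rule then degrades, which
  is logged).
* A cluster whose spots would fall outside the frame raises a spec error
  naming the cluster rather than silently clipping.

## Known limitations

* Orientation gaps of the 8-line bank and the separable transform's weak
  oblique selectivity mean strongly curved or obliquely oriented thin
  structure survives both stages; suppression then rests on the
  fragment-size filter and the ≥ 4-per-block rule.
* Spots below ~0.3 mm at 0.05 mm/pixel live in the zeroed finest band
  and are attenuated below the default floor — a property of the
  subband-zeroing design, not of the implementation. Detecting them
  requires retaining the finest details (reconfigure the selector) and a
  different false-positive strategy.
* No candidate-level classification (shape, contrast, texture) is
  performed; the component count per block is the only cluster evidence,
  as in the original formulation of this detector.
* TPR on a suite is reported to 1 decimal in percent and FP/image to 2
  decimals; with no true clusters TPR is reported as undefined, never
  as 100 %.
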