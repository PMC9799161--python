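# Methods

## The glare model

The package implements the CIE general disability glare equation (the
age- and pigment-parameterized standard for intraocular straylight),
valid from 0.1 arcmin to beyond 60° of angular separation. Its three
components describe, in order, small-angle forward scatter in the ocular
media (dominant below ~0.1°, slightly attenuated with age), wide-angle
stray light including the iris/sclera translucency term scaled by the
pigmentation factor `p` (amplified with age), and a constant
pigment-dependent floor. Parameters:

| parameter | meaning | default | why |
|---|---|---|---|
| `age` | observer age, years | 25 | young observer, minimal-glare prediction |
| `pigment` | iris pigmentation `p` (0 very dark … ~1.2 light) | 0.5 | brown eyes |
| `field_of_view_deg` | visual angle of the larger image dimension | 10° (20° for the double-width target) | stimulus viewed at 24 in; 2048 px over 10° = 0.293 arcmin/pixel |

The function is strictly decreasing, strictly positive, and has no
asymptote, which forces the *full-image kernel*: radius
`max(rows, cols) + 1` pixels, so the kernel centered on any pixel covers
the entire image.

Two modeling choices close gaps the standard leaves open for discrete
planar images:

- **Zero-offset weight.** The equation diverges at θ = 0; the center
  weight is evaluated at half a pixel pitch. Any finite choice is
  absorbed by the subsequent normalization; half a pitch is the natural
  resolution scale.
- **Sphere-to-plane mapping.** The GSF is defined on visual angle; the
  stimulus is planar. A planar offset of `d` pixels maps to
  θ = atan(d·tan(pitch)). No solid-angle Jacobian is applied: the
  kernel is normalized to unit sum afterwards, so only the *shape* of
  the fall-off matters, and the mapping is isolated in one function so
  alternatives can be swapped.

After normalization the kernel sums to 1 within 10⁻¹², every weight is
positive, the center is the maximum, and the array is symmetric under
horizontal/vertical flips. Kernels are cached per geometry (an 8195²
kernel takes seconds to build and ~0.5 GB).

A note on the printed per-pixel angle: 10° over 2048 pixels is
0.293 arcmin/pixel; a figure-caption value of 0.24 arcmin circulates for
the same setup but is inconsistent with its own field of view, so the
field-of-view-derived value is used throughout.

## The convolution

Retinal contrast is the *linear* convolution of the normalized scene
with the kernel, never a circular one. The scene is padded on each side
by the kernel radius `r`:

- `replicate` (default, the reproduction mode): the outer rim is
  repeated, equivalent to displaying the stimulus at the center of a
  uniform surround of its own border values, nine times the stimulus
  area. A white-bordered target is thereby computed "on a white
  screen", a black-bordered one "in a darkroom".
- `constant(value)`: idealized uniform surrounds, provided for testing.

For a padded array of size `P = N + 2r` and a kernel of half-width `r`,
a circular FFT convolution at transform size ≥ `P` is already exact
linear convolution on the central `N` crop -- no kernel tap centered
there can reach across the transform boundary. Transforms therefore run
at `next_fast_len(P)` instead of the full `P + 2r` linear-convolution
size, roughly halving time and memory (the 4096×2048 target peaks at
~3.9 GB). The FFT path is validated against a direct spatial sum and
against an independent implementation (`scipy.ndimage.convolve`) to
1e-10 relative on small instances, for both padding modes. All
arithmetic is 64-bit; tiny negative FFT round-off (≲1e-16) is clamped to
zero before analysis.

**Energy accounting.** The unit-sum kernel introduces no energy: for a
uniform image, output equals input to 1e-15. For non-uniform images
energy crosses the image border in both directions: about 3% of the
kernel mass lies beyond the border for central pixels, so the ratio
sum(out)/sum(in) deviates from 1 by (surround mean − image mean) ×
(mean outside mass). For the illusion targets, whose outer bands are
pure White or Black while the image mean is mid-range, the measured
ratios are +1.1…+1.4% (white bands) and −1.7% (black bands). This is
physical boundary flux of the prescribed replicate padding, not a
numerical defect; a stricter ±0.5% conservation band holds only for
images whose border matches their mean.

## Range mapping and analysis conventions

- `log_map`: digit = round(255·(1 + log₁₀(v/vmax)/range)), clipped to
  [0, 255]; `percent_of_range` is the same on a 0–100 scale. The
  default range is 2.3 log₁₀ units (200:1). `vmax` is **per image** --
  scene and retina each scale to their own maximum, so digit 255 means
  "this image's peak" in both panels.
- Rounding is half-away-from-zero, applied exactly once at
  quantization. Values below the range floor clip to digit 0, which is
  what produces the abrupt digit floors seen in range-limited retinas.
- ROI statistics are reported for the full mask and for the mask eroded
  by 2 pixels (default convention): the outermost pixels of a segment
  carry extreme edge-gradient values that describe the boundary, not
  the region. If erosion would empty a mask, the full mask is used.
- Histograms: 256 bins, each normalized to its own peak; `linear` mode
  bins linear values over [0, max], `log` mode bins log₁₀(v/max) over
  [−range, 0] with sub-floor values clipped into the lowest bin. Both
  modes are always computed, since "linear histogram" is ambiguous
  between them.
- `image_range` is 100·log₁₀(max/min)/range, clipped to [0, 100].
- A Glare's-Paradox report compares mean *linear* retinal contrast of a
  declared (darker, lighter) appearance pair; the paradox flag is a
  strict inequality, and appearance orderings are declared by the
  stimulus generators, never inferred -- the package models no
  appearances.

## Pseudocolor tables

The 64-band `cmap` groups digits by band = clip(round(d/4), 0, 63):
62 interior bands of exactly 4 digits plus end bands of 2 and 6 (the
rounding that produces the documented grouping of digits 194–197 into
one band necessarily leaves uneven end bands). Bands are built as 8 hue
progressions × 8 steps, ordered dark-to-bright so lightness order
survives; the progression ramps are this package's own choice except for
the pinned anchor, band 49 = RGB [192, 255, 64], the green band that
display-Gray (digit 197 after log mapping) falls into. The full table
is replaceable from a 256-row CSV. The 3-3-2 RGB table is the standard
bit partition (red top 3 bits, green next 3, blue low 2, each shifted to
8 bits), giving 256 distinct colors, black at 0 and yellow-tinted
maximum at 255 -- maximal gradient visibility, no lightness order. The
quadrant superposition composite overlays four renderings and paints a
supplied boundary mask pure red to locate scene edges inside retinal
gradients.

## The stimulus generators

The generators are the package's synthetic data; they emulate the
published stimulus *family* under the study conditions rather than
pixel-copying artwork that exists only as figures.

**What is fixed by the printed record** (and asserted by tests): display
luminances White 450 / Gray 136 / Black 2.24 cd/m² (200:1, log 2.3);
2048² maps at 10°; area fractions Gray 14% in all variants, White/Black
57/29% (A, B) and 29/57% (C, D); outer-band colors (White for A/B,
Black for C/D); A's Contrast surrounds larger than B's, C's larger than
D's; identical Gray locations across variants; Todorović at 4096×2048
(20°×10°) with cross arms 380×25 px and Contrast circles 46 arcmin from
the nearest max/min edge; Mondrian circles exactly equal in scene
luminance at 80% of the log range, bottom of the gradient brighter.

**What is reconstructed**: every dimension the figures do not print.
The Contrast surrounds, stripe field, and a per-variant balancing band
are solved by a small fixed-point iteration at build time so the printed
fractions hold within 1% of total pixels at any size ≥ 512 (the solver's
few free dimensions are recorded in the bundle metadata). The Todorović
background -- a fourth luminance the record calls only "light gray" --
is fixed once at 100 cd/m² (22% of White), the value consistent with the
published global retinal range of that target, with its circles placed
on one shared Black|White panel as the 46-arcmin edge distance requires.
The Mondrian is a seeded guillotine tiling (default 120 patches,
reflectances 0.04–0.92) under an exponential vertical illumination
gradient of 0.65 log units -- the steepest gradient for which the two
equated circle papers stay within physical reflectance bounds; the two
circle regions share one display digit (88 on a linear calibration), so
their luminance equality is exact rather than approximate, and survives
image negation.

**What the synthetic stimuli do not capture**: the exact figure artwork
(surround proportions are constraint-solved, not traced), display
nonuniformity and measurement noise (calibrations are exact tables), and
external images such as the Checkershadow -- those enter only as
user-supplied calibrated maps. Passing tests therefore establish that
the *method* reproduces the published glare phenomenology on faithful
reconstructions, not that any specific published pixel array was
recovered. One consequence: the Mondrian's per-circle retinal percents
come out 80.0/80.5 rather than the published 78/84 -- the correct
ordering and paradox with a smaller margin, because the reconstructed
gradient is capped at 0.65 log units by reflectance feasibility.

## Problem sizes and determinism

Reproduction computations run at the published scales (2048² and
4096×2048); unit and property tests use toy geometries (9–32 px) where
brute-force oracles are exact and cheap. A full-scale convolution takes
~5 s (square) to ~30 s (double width) on one CPU; the acceptance script
recomputes everything in a few minutes. All generators are
deterministic given their arguments; the Mondrian takes an explicit
seed, and identical configurations produce bit-identical pipeline
outputs (checksummed in the run manifest).

## Known limitations

- No pupil-size model, pre-retinal absorption, or wavelength dependence:
  *retinal contrast* is relative light, not retinal luminance.
- No appearance or neural-processing model; paradox reports compare
  physics against *declared* appearance orderings.
- No tiled/streaming convolution: images much larger than 4096×2048
  will exhaust memory (the kernel build enforces a configurable cap).
- The replicate-padding surround is a modeling idealization of "the
  stimulus on its own border color"; real viewing rooms differ.
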