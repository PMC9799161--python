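# retinaglare

**The pattern of light on the retina behind a displayed stimulus.**

Lightness illusions start from a "null experiment": two scene segments
with *identical* luminance that nevertheless look different. But identical
luminances at the display are not identical lights at the receptors.
Before any neural processing, intraocular veiling glare redistributes the
scene's light across the retina: every pixel receives a tiny scattered
contribution from every other pixel, and the millions of contributions
sum to a scene-dependent transformation of the stimulus.

`retinaglare` computes that transformation. It converts a calibrated
8-bit display stimulus into **retinal contrast** -- the normalized linear
light distribution on the receptors -- by convolving scene luminance with
the CIE age/pigment-parameterized **glare spread function** (GSF), and
then quantifies what glare did: dynamic ranges, ROI statistics,
histograms, scan-line profiles, pseudocolor renderings, and
*Glare's-Paradox* reports. It is written for vision scientists studying
lightness, glare, HDR imaging, or image quality, who need the actual
receptor-level input to their models rather than the zero-glare idealization.

## The model

The CIE general disability glare equation gives the equivalent veiling
luminance per unit glare illuminance, `Leq/Egl`, between two retinal
locations separated by visual angle θ (degrees), for an observer of age
`A` years and iris pigmentation `p`:

```
Leq/Egl = [1 − 0.08(A/70)⁴] · [ 9.2·10⁶ / (1 + (θ/0.0046)²)^1.5
                              + 1.5·10⁵ / (1 + (θ/0.045)²)^1.5 ]
        + [1 + 1.6(A/70)⁴] · [ 400 / (1 + (θ/0.1)²) + 3·10⁻⁸·θ²
                              + p·(1300 / (1 + (θ/0.1)²)^1.5
                                 + 0.8 / (1 + (θ/0.1)²)^0.5) ]
        + 2.5·10⁻³·p
```

It spans ~8 log₁₀ units between 1 arcmin and 60° and never reaches an
asymptote, so the convolution kernel must cover the whole image: its
radius is the larger image dimension plus one pixel, and its weights are
normalized to unit sum so the convolution redistributes light without
creating any. The retinal image is then

```
retinal_contrast = scene_luminance ⊛ GSF-kernel
```

computed as a wrap-free linear convolution (FFT-based, with
boundary-replication padding: the stimulus behaves as if displayed at
the center of a uniform surround of its own border values). Defaults
reproduce a young, brown-eyed observer: age 25, pigment 0.5. Pupil size
and pre-retinal absorption are outside the model, and no claim is made
about *appearance* -- the package stops at the light on the receptors.

Analysis uses the **log-range convention**: images are expressed on the
scene's log range (default 2.3 log₁₀ units = the 200:1 display range),
either as 8-bit log-mapped digits or as percent-of-range (100% = image
maximum, 0% = maximum/200).

## A worked example

```python
import retinaglare as rg

bundle = rg.make_contrast_assimilation("A")     # 2048², 10° of visual angle
kernel = rg.get_kernel(bundle.geometry)         # CIE GSF, age 25, pigment 0.5
retina = rg.convolve(bundle.scene_luminance(), kernel)

print(f"retina range: {rg.image_range(retina):.1f}% of 2.3 log units")
for rep in rg.paradox_report(retina, bundle):
    tag = "GLARE'S PARADOX" if rep.paradox else "no paradox"
    print(rep.roi_darker, rep.mean_darker, rep.mean_lighter, tag)
```

prints

```
retina range: 66.1% of 2.3 log units
gray_in_white_contrast       0.3985 vs 0.2803  -> GLARE'S PARADOX
gray_in_black_assimilation   0.3215 vs 0.4800  -> no paradox
```

Reading: the 200:1 scene range collapsed to 66% of its log range on the
retina (glare filled the blacks). In the Contrast pair, the gray that
*appears darker* (on the White surround) received **more** light --
that is Glare's Paradox: neural processing overcompensates the optics.
In the Assimilation pair the gray that appears darker received less
light, so assimilation shows no paradox. The two gray ROIs, identical
in the scene, became retinal gradients spanning 80–92% and 67–77% of
the log range respectively.

The `examples/` directory has one short script per capability
(`gsf_curve.py`, `contrast_illusion.py`, `mondrian_paradox.py`,
`pseudocolor_square.py`); each prints what it computes and what the
numbers mean. A thin CLI wraps the same pipeline:

```
retinaglare targets make A --out targetA/        # stimulus + calibration + ROIs
retinaglare run config.yaml                      # full eight-image analysis run
retinaglare analyze scene.tif retina.tif --rois masks/
```

## Built-in stimuli

All inputs are generated, none downloaded: four Contrast+Assimilation
targets (A–D: White or Black outer bands, large or small Contrast
surrounds, fixed 14/57/29% area fractions), the Todorović
circles-and-crosses target (4096×2048, 20°×10°), a centered max/min
square for LUT demonstrations, a seeded black-and-white Mondrian with an
illumination gradient equating two circle ROIs at 80% of the log range,
and photographic negatives of any of them. Each generator returns the
digit map, display calibration, ROI masks, and the declared appearance
ordering, so the paradox analysis is self-contained. User-supplied
stimuli enter through an 8-bit TIFF/PNG plus a `digit,cd_per_m2`
calibration CSV.

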