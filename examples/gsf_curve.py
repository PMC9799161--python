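"""The glare spread function itself: how fast scattered light falls off.

Evaluates the CIE disability glare equation for a young brown-eyed
observer (age 25, pigment 0.5) across the full angular range and prints
the numbers that characterize it.  Leq/Egl is the equivalent veiling
luminance a glare source produces per unit illuminance at the eye: large
at arcminute separations, tiny but never zero at 60 degrees -- which is
why every scene pixel contributes glare to every other pixel.
"""

import math

import retinaglare as rg

for theta in (1 / 60, 0.1, 1.0, 10.0, 60.0):
    print(f"theta = {theta:8.4f} deg   Leq/Egl = {rg.gsf_value(theta):12.5g}")

span = math.log10(rg.gsf_value(1 / 60) / rg.gsf_value(60.0))
print(f"\nspan from 1 arcmin to 60 deg: {span:.2f} log10 units (~8 decades)")
print("the function is strictly decreasing and never reaches an asymptote,")
print("so the convolution kernel must cover the entire image.")

kernel = rg.build_kernel(rg.AngularGeometry((256, 256), field_of_view_deg=10.0))
print(f"\n256x256 geometry -> kernel of {kernel.side}x{kernel.side} weights, "
      f"sum = {kernel.weights.sum():.15f}")
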