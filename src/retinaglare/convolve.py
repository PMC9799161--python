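"""Wrap-free FFT convolution of scene luminance with the glare kernel.

The retinal image is the linear convolution of the scene with the
unity-normalized glare kernel.  A naive circular FFT convolution would
wrap light around the image borders, so the scene is first padded on each
side by the kernel radius -- by replicating its outer rim (the
reproduction mode: the stimulus behaves as if displayed at the center of
a uniform surround of its own border values, nine times the stimulus
area) or with a constant (darkroom / whiteroom idealizations).

For the padded array of size ``P = N + 2r`` and a kernel of half-width
``r``, a circular convolution at transform size >= P is already exact
linear convolution on the central ``N`` crop: no kernel tap centered
there can reach across the transform boundary.  This keeps transform
sizes (and memory) far below the full ``P + 2r`` linear-convolution size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .gsf import GlareKernel

__all__ = ["PaddingMode", "REPLICATE", "convolve", "RetinalContrast"]


@dataclass(frozen=True)
class PaddingMode:
    """Boundary treatment for the convolution.

    ``mode='replicate'`` repeats the image's outer rim (the default and
    the only mode used for reproducing displayed-stimulus results);
    ``mode='constant'`` embeds the image in a uniform field of ``value``.
    """

    mode: str = "replicate"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("replicate", "constant"):
            raise ValueError(f"padding mode must be 'replicate' or 'constant', got {self.mode!r}")


REPLICATE = PaddingMode("replicate")


@dataclass(frozen=True)
class RetinalContrast:
    """Light-on-retina array: positive, 64-bit, same shape as the scene."""

    values: np.ndarray
    padding: PaddingMode
    energy_ratio: float  # sum(output) / sum(input)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sidecar(self) -> dict:
        return {
            "padding": self.padding.mode,
            "padding_value": self.padding.value,
            "energy_ratio": self.energy_ratio,
            "min": float(self.values.min()),
            "max": float(self.values.max()),
            "linear_convolution": True,
        }


def _pad(values: np.ndarray, radius: int, padding: PaddingMode) -> np.ndarray:
    if padding.mode == "replicate":
        return np.pad(values, radius, mode="edge")
    return np.pad(values, radius, mode="constant", constant_values=padding.value)


def convolve(scene, kernel: GlareKernel, padding: PaddingMode = REPLICATE) -> RetinalContrast:
    """Convolve a normalized scene-luminance array with the glare kernel.

    Parameters
    ----------
    scene
        A ``SceneLuminance`` (anything with a 2-D ``values`` array) or a
        bare 2-D array, finite and non-negative, whose shape matches the
        geometry the kernel was built for.
    kernel
        Full-image kernel from :func:`retinaglare.gsf.build_kernel`.
    padding
        Boundary treatment; replicate by default.

    Returns
    -------
    RetinalContrast
        Same shape as the input, 64-bit, all values positive for positive
        input.  Because the kernel is a positive unit-sum averaging
        operator, output values stay within the padded input's [min, max].
    """
    values = np.asarray(getattr(scene, "values", scene), dtype=np.float64)
    if values.ndim != 2:
        raise ValueError(f"scene must be 2-D, got shape {values.shape}")
    if values.shape != tuple(kernel.geometry.image_shape):
        raise ValueError(
            f"scene shape {values.shape} does not match kernel geometry {kernel.geometry.image_shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("scene contains non-finite values")

    r = kernel.radius_px
    padded = _pad(values, r, padding)
    pr, pc = padded.shape
    fr = scipy.fft.next_fast_len(pr, real=True)
    fc = scipy.fft.next_fast_len(pc, real=True)

    spec = scipy.fft.rfft2(padded, s=(fr, fc))
    del padded
    kspec = scipy.fft.rfft2(kernel.weights, s=(fr, fc))
    spec *= kspec
    del kspec
    out = scipy.fft.irfft2(spec, s=(fr, fc))
    del spec
    # output index j = i + 2r collects kernel taps over padded[i .. i+2r]
    rows, cols = values.shape
    result = np.ascontiguousarray(out[2 * r : 2 * r + rows, 2 * r : 2 * r + cols])
    del out
    # FFT round-off can leave tiny negatives where the true value is ~0
    np.maximum(result, 0.0, out=result)
    in_sum = float(values.sum())
    ratio = float(result.sum()) / in_sum if in_sum > 0 else float("nan")
    return RetinalContrast(values=result, padding=padding, energy_ratio=ratio)


def convolve_spatial(scene, kernel: GlareKernel, padding: PaddingMode = REPLICATE) -> np.ndarray:
    """Direct O(N^2) spatial-domain convolution (small inputs only).

    Reference path for validating the FFT route; identical padding
    semantics.  Cost grows with image area times kernel area -- use on
    toy instances.
    """
    values = np.asarray(getattr(scene, "values", scene), dtype=np.float64)
    r = kernel.radius_px
    padded = _pad(values, r, padding)
    rows, cols = values.shape
    out = np.zeros((rows, cols), dtype=np.float64)
    w = kernel.weights
    side = kernel.side
    for dy in range(side):
        for dx in range(side):
            out += w[side - 1 - dy, side - 1 - dx] * padded[dy : dy + rows, dx : dx + cols]
    return out
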