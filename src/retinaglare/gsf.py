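"""CIE glare spread function and full-image convolution kernel.

The CIE general disability glare equation gives the equivalent veiling
luminance per unit glare illuminance at the eye, ``Leq/Egl``, as a function
of the angular separation ``theta`` (degrees) between a glare source and
the receiving retinal location.  It is parameterized by observer age in
years and an iris-pigmentation factor ``p`` (0 for very dark eyes, 0.5 for
brown, ~1.0-1.2 for light eyes).  The equation is valid from 0.1 arcmin to
100 degrees, is strictly decreasing, and never reaches zero or a constant
asymptote -- every scene pixel contributes glare to every other pixel.

``build_kernel`` turns the radial function into a normalized 2-D
convolution kernel whose radius equals the larger image dimension plus one
pixel, so that the kernel centered on any pixel covers the whole image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "GlareParameters",
    "AngularGeometry",
    "GlareKernel",
    "gsf_value",
    "build_kernel",
]

#: soft limit on kernel memory, in bytes (float64 weights)
DEFAULT_KERNEL_MEMORY_LIMIT = 2 * 1024**3


class GlareDomainError(ValueError):
    """Raised for angular or parameter values outside the GSF's domain."""


class KernelMemoryError(MemoryError):
    """Raised when a requested kernel would exceed the configured limit."""


@dataclass(frozen=True)
class GlareParameters:
    """Observer parameters of the CIE disability glare equation.

    Defaults are a young observer with brown eyes (age 25, pigment 0.5),
    i.e. minimal-glare vision.
    """

    age: float = 25.0
    pigment: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise GlareDomainError(f"age must be a positive finite number of years, got {self.age!r}")
        if not (math.isfinite(self.pigment) and self.pigment >= 0):
            raise GlareDomainError(f"pigment must be a finite non-negative factor, got {self.pigment!r}")


@dataclass(frozen=True)
class AngularGeometry:
    """Angular calibration of a stimulus image.

    The image's larger dimension spans ``field_of_view_deg`` of visual
    angle; the per-pixel pitch follows from that.  The default calibration
    used throughout is 10 degrees over 2048 pixels = 0.293 arcmin/pixel.
    """

    image_shape: tuple[int, int]
    field_of_view_deg: float = 10.0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 2 or cols < 2:
            raise ValueError(f"image_shape must be at least 2x2, got {self.image_shape}")
        if not (math.isfinite(self.field_of_view_deg) and self.field_of_view_deg > 0):
            raise ValueError(f"field_of_view_deg must be positive, got {self.field_of_view_deg!r}")

    @property
    def arcmin_per_pixel(self) -> float:
        return self.field_of_view_deg * 60.0 / max(self.image_shape)

    @property
    def pixel_pitch_deg(self) -> float:
        return self.arcmin_per_pixel / 60.0


def gsf_value(theta_deg, params: GlareParameters = GlareParameters()):
    """Evaluate the CIE general disability glare equation.

    Parameters
    ----------
    theta_deg : float or ndarray
        Angular separation between donor and receiving pixel, in degrees.
        Must be strictly positive (the equation diverges at zero).
    params
        Observer age and iris pigmentation.

    Returns
    -------
    float or ndarray
        ``Leq/Egl``, the dimensionless relative veiling luminance.  Always
        positive and strictly decreasing in ``theta_deg``.
    """
    theta = np.asarray(theta_deg, dtype=np.float64)
    if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
        bad = theta[~(np.isfinite(theta) & (theta > 0))]
        raise GlareDomainError(
            f"theta_deg must be positive and finite; offending value(s): {np.atleast_1d(bad)[:5]!r}"
        )
    age4 = (params.age / 70.0) ** 4
    p = params.pigment

    t2 = theta * theta
    # dominant small-angle scatter (cornea / lens forward scatter)
    term_small = 9.2e6 / (1.0 + t2 / 0.0046**2) ** 1.5 + 1.5e5 / (1.0 + t2 / 0.045**2) ** 1.5
    # wide-angle stray light, with iris/sclera translucency scaled by pigment
    q = 1.0 + t2 / 0.1**2
    term_wide = (400.0 / q + 3.0e-8 * t2) + p * (1300.0 / q**1.5 + 0.8 / np.sqrt(q))
    out = (1.0 - 0.08 * age4) * term_small + (1.0 + 1.6 * age4) * term_wide + 2.5e-3 * p
    if np.isscalar(theta_deg):
        return float(out)
    return out


@dataclass(frozen=True)
class GlareKernel:
    """Unity-normalized 2-D glare kernel covering a whole image.

    ``weights`` has odd side ``2*radius_px + 1`` and sums to one; the
    maximum sits at the center and the array is symmetric under horizontal
    and vertical flips (radial function sampled on the pixel grid).
    """

    weights: np.ndarray = field(repr=False)
    radius_px: int
    geometry: AngularGeometry
    params: GlareParameters
    normalization_sum: float  # raw sum of unnormalized weights

    @property
    def side(self) -> int:
        return 2 * self.radius_px + 1

    def sidecar(self) -> dict:
        """JSON-serializable provenance record for kernel exports."""
        return {
            "radius_px": self.radius_px,
            "side": self.side,
            "image_shape": list(self.geometry.image_shape),
            "field_of_view_deg": self.geometry.field_of_view_deg,
            "arcmin_per_pixel": self.geometry.arcmin_per_pixel,
            "age": self.params.age,
            "pigment": self.params.pigment,
            "normalization_sum": self.normalization_sum,
            "normalized_sum": float(self.weights.sum()),
        }


def _pixel_distance_to_theta_deg(distance_px, pitch_deg: float):
    """Map planar pixel distance to visual angle in degrees.

    The GSF describes light projected on a sphere around the eye; the
    stimulus and retina arrays are planar.  A planar offset of ``d`` pixels
    at per-pixel pitch ``pitch_deg`` subtends ``atan(d * tan(pitch))``.
    Isolated here so the sphere-to-plane mapping can be swapped; the
    kernel's unity normalization absorbs any global scale factor.
    """
    return np.degrees(np.arctan(np.asarray(distance_px, dtype=np.float64) * math.tan(math.radians(pitch_deg))))


def build_kernel(
    geometry: AngularGeometry,
    params: GlareParameters = GlareParameters(),
    *,
    memory_limit_bytes: int = DEFAULT_KERNEL_MEMORY_LIMIT,
) -> GlareKernel:
    """Build the normalized full-image glare kernel for a geometry.

    The kernel radius is ``max(rows, cols) + 1`` pixels so that, centered
    on any corner pixel, the kernel still covers the entire image.  Each
    weight is the GSF evaluated at the angle subtended by that pixel
    offset; the zero-offset (center) weight is evaluated at half a pixel
    pitch, a finite resolution-consistent stand-in for the equation's
    divergence at zero.  Weights are then divided by their total so they
    sum to unity: the convolution redistributes light without creating any.
    """
    radius = max(geometry.image_shape) + 1
    side = 2 * radius + 1
    est = side * side * 8
    if est > memory_limit_bytes:
        raise KernelMemoryError(
            f"kernel of side {side} needs {est / 1e9:.2f} GB > limit {memory_limit_bytes / 1e9:.2f} GB"
        )
    pitch = geometry.pixel_pitch_deg
    # radial symmetry: evaluate one quadrant (plus axes) and mirror
    ax = np.arange(radius + 1, dtype=np.float64)
    dist = np.hypot(ax[:, None], ax[None, :])
    dist[0, 0] = 0.5  # center evaluated at half a pixel pitch
    quad = gsf_value(_pixel_distance_to_theta_deg(dist, pitch), params)
    weights = np.empty((side, side), dtype=np.float64)
    weights[radius:, radius:] = quad
    weights[radius:, :radius] = quad[:, :0:-1]
    weights[:radius, :] = weights[:radius:-1, :]
    raw_sum = float(weights.sum())
    weights /= raw_sum
    weights.setflags(write=False)
    return GlareKernel(
        weights=weights,
        radius_px=radius,
        geometry=geometry,
        params=params,
        normalization_sum=raw_sum,
    )


@lru_cache(maxsize=2)
def _cached_kernel(shape: tuple[int, int], fov: float, age: float, pigment: float) -> GlareKernel:
    return build_kernel(AngularGeometry(shape, fov), GlareParameters(age, pigment))


def get_kernel(geometry: AngularGeometry, params: GlareParameters = GlareParameters()) -> GlareKernel:
    """Kernel for a geometry, cached (kernels are expensive to build)."""
    return _cached_kernel(tuple(geometry.image_shape), geometry.field_of_view_deg, params.age, params.pigment)


def export_kernel(kernel: GlareKernel, tiff_path, sidecar_path=None) -> None:
    """Write the kernel as a 64-bit float TIFF plus a JSON sidecar."""
    import tifffile

    tifffile.imwrite(str(tiff_path), kernel.weights)
    if sidecar_path is None:
        sidecar_path = str(tiff_path) + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump(kernel.sidecar(), fh, indent=2)
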