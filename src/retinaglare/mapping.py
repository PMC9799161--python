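"""Log-range mapping of linear images for 8-bit analysis renderings.

The convolution's 64-bit linear arrays cannot be displayed or compared
directly; for analysis they are rescaled logarithmically to a chosen
``log_range`` (default 2.3 log10 units = the 200:1 display range).  Digit
255 is the image's own maximum, digit 0 is ``max * 10**(-range)``, and
everything below the range floor clips to 0 (the "abrupt lower range
limit" that appears as a digit floor in range-limited images).

The same convention expressed on a 0-100 scale, *percent of log range*,
is the unit used for all region-of-interest comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LogRange", "LogMappedImage", "log_map", "percent_of_range"]


@dataclass(frozen=True)
class LogRange:
    """Log10 span to which analysis images are scaled (default 2.3 = 200:1)."""

    range_log10: float = 2.3

    def __post_init__(self) -> None:
        if not (np.isfinite(self.range_log10) and self.range_log10 > 0):
            raise ValueError(f"log range must be positive and finite, got {self.range_log10!r}")

    @property
    def linear_ratio(self) -> float:
        return 10.0**self.range_log10


@dataclass(frozen=True)
class LogMappedImage:
    """8-bit log-scaled rendering bound to the log range it was scaled to."""

    digits: np.ndarray = field(repr=False)
    log_range: LogRange

    @property
    def shape(self) -> tuple[int, int]:
        return self.digits.shape

    def sidecar(self) -> dict:
        return {"log_range": self.log_range.range_log10, "digit_255": "image maximum"}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # quantization applied exactly once; ties round away from zero
    return np.floor(x + 0.5)


def _values_of(image) -> np.ndarray:
    return np.asarray(getattr(image, "values", image), dtype=np.float64)


def log_map(image, log_range: LogRange = LogRange()) -> LogMappedImage:
    """Map a positive linear image to 8-bit log digits.

    ``digit = round(255 * (1 + log10(v / vmax) / range))`` clipped to
    [0, 255]; ``vmax`` is the image's own maximum (scene and retina are
    each scaled to their own peak).
    """
    v = _values_of(image)
    vmax = v.max()
    if not vmax > 0:
        raise ValueError("log mapping needs an image with positive maximum")
    with np.errstate(divide="ignore"):
        rel = np.log10(v / vmax)
    digits = _round_half_away(255.0 * (1.0 + rel / log_range.range_log10))
    digits = np.clip(digits, 0, 255).astype(np.uint8)
    return LogMappedImage(digits=digits, log_range=log_range)


def percent_of_range(value, vmax, log_range: LogRange = LogRange()):
    """Express a positive value as percent of the log range below ``vmax``.

    100 is the maximum, 0 is ``vmax * 10**(-range)``.  Values above
    ``vmax`` clip to 100 with a warning; values below the floor clip to 0.
    """
    value = np.asarray(value, dtype=np.float64)
    if np.any(value <= 0):
        raise ValueError("percent_of_range needs positive values")
    if np.any(value > vmax):
        warnings.warn("value above vmax clipped to 100% of range", stacklevel=2)
    pct = 100.0 * (1.0 + np.log10(value / vmax) / log_range.range_log10)
    pct = np.clip(pct, 0.0, 100.0)
    return float(pct) if pct.ndim == 0 else pct
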