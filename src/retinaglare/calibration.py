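"""Display calibration: from 8-bit digit maps to linear scene luminance.

A stimulus exists in two forms: the 8-bit *digit map* sent to the display,
and the array of luminances (cd/m^2) the display actually emits, measured
with a telephotometer at a set of digit values.  ``apply_calibration``
joins the two into the normalized linear ``SceneLuminance`` array that the
glare convolution consumes: each digit is mapped through monotone
piecewise-linear interpolation of the measured samples and the result is
divided by its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DigitMap",
    "DisplayCalibration",
    "SceneLuminance",
    "load_digit_map",
    "apply_calibration",
    "default_display_calibration",
]


class FormatError(ValueError):
    """Raised for unusable image input (wrong depth, channels, missing)."""


class CalibrationCoverageError(ValueError):
    """Raised when a digit map contains digits above the calibrated span."""


@dataclass(frozen=True)
class DigitMap:
    """2-D array of 8-bit display digits."""

    digits: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.digits)
        if d.ndim != 2:
            raise FormatError(f"digit map must be 2-D grayscale, got shape {d.shape}")
        if d.dtype != np.uint8:
            if not np.issubdtype(d.dtype, np.integer) or d.min() < 0 or d.max() > 255:
                raise FormatError(f"digit values must be integers in [0, 255], got dtype {d.dtype}")
            object.__setattr__(self, "digits", d.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.digits.shape


def load_digit_map(path) -> DigitMap:
    """Read an 8-bit grayscale TIFF or PNG as a :class:`DigitMap`.

    Multi-channel (RGB/RGBA) and non-8-bit inputs are rejected: stimulus
    maps are single-channel digit arrays by construction.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected single-channel grayscale, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path.name}: expected 8-bit data, got {arr.dtype}")
    return DigitMap(arr)


def save_digit_map(map_: DigitMap, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), map_.digits)


@dataclass(frozen=True)
class DisplayCalibration:
    """Measured (digit, cd/m^2) samples of a display, strictly increasing.

    Between samples the display response is interpolated piecewise-linearly;
    a fully sampled 256-entry table bypasses interpolation entirely.
    """

    samples: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        s = tuple((int(d), float(L)) for d, L in self.samples)
        if len(s) < 2:
            raise ValueError("calibration needs at least two (digit, luminance) samples")
        digits = [d for d, _ in s]
        lums = [L for _, L in s]
        if any(b <= a for a, b in zip(digits, digits[1:])):
            raise ValueError(f"calibration digits must be strictly increasing, got {digits}")
        if any(b <= a for a, b in zip(lums, lums[1:])):
            raise ValueError(f"calibration luminances must be strictly increasing, got {lums}")
        if lums[0] <= 0:
            raise ValueError("calibrated luminances must be positive")
        object.__setattr__(self, "samples", s)

    @property
    def digit_span(self) -> tuple[int, int]:
        return self.samples[0][0], self.samples[-1][0]

    @property
    def luminance_range(self) -> float:
        """Linear max/min luminance ratio of the calibrated span."""
        return self.samples[-1][1] / self.samples[0][1]

    def luminance(self, digits) -> np.ndarray:
        """Interpolated cd/m^2 for an array of digits.

        Digits below the calibrated black point are clamped to the lowest
        calibrated luminance with a warning (tolerates antialiased edges
        in user images); digits above the calibrated white are an error.
        """
        d = np.asarray(digits, dtype=np.float64)
        lo, hi = self.digit_span
        if np.any(d > hi):
            raise CalibrationCoverageError(
                f"digit map contains digits above the calibrated span (max sampled digit {hi})"
            )
        if np.any(d < lo):
            warnings.warn(
                f"digits below calibrated black point ({lo}) clamped to {self.samples[0][1]} cd/m^2",
                stacklevel=2,
            )
        xs = np.array([s[0] for s in self.samples], dtype=np.float64)
        ys = np.array([s[1] for s in self.samples], dtype=np.float64)
        return np.interp(d, xs, ys)

    @classmethod
    def from_csv(cls, path) -> "DisplayCalibration":
        df = pd.read_csv(path)
        missing = {"digit", "cd_per_m2"} - set(df.columns)
        if missing:
            raise ValueError(f"calibration CSV must have columns digit,cd_per_m2 (missing {sorted(missing)})")
        return cls(tuple(zip(df["digit"].astype(int), df["cd_per_m2"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.samples, columns=["digit", "cd_per_m2"]).to_csv(path, index=False)


def default_display_calibration() -> DisplayCalibration:
    """Measured calibration of the illusion display.

    White digit 255 -> 450 cd/m^2, Gray 145 -> 136, Black 21 -> 2.24; a
    200:1 (2.3 log10 unit) luminance range.
    """
    return DisplayCalibration(((21, 2.24), (145, 136.0), (255, 450.0)))


@dataclass(frozen=True)
class SceneLuminance:
    """Normalized linear scene luminance: 64-bit, max exactly 1.

    ``max_cd_m2`` records the absolute luminance of the normalization
    anchor so absolute units can be recovered.
    """

    values: np.ndarray = field(repr=False)
    max_cd_m2: float

    def __post_init__(self) -> None:
        v = self.values
        if v.dtype != np.float64:
            raise TypeError("scene luminance must be float64")
        if v.max() != 1.0:
            raise ValueError("scene luminance must be normalized to max = 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def apply_calibration(map_: DigitMap, cal: DisplayCalibration) -> SceneLuminance:
    """Map digits through the display calibration and normalize to max 1."""
    lum = cal.luminance(map_.digits)
    peak = float(lum.max())
    out = lum / peak
    out[np.unravel_index(out.argmax(), out.shape)] = 1.0  # guard float64 round-off
    return SceneLuminance(values=out, max_cd_m2=peak)
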