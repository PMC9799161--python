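"""Pseudocolor lookup tables for visualizing glare gradients.

Post-glare luminance gradients are mostly below visual detection
threshold in a grayscale rendering; a pseudocolor LUT with visible
quantization steps turns them into discriminable bands of color.  Two
tables are provided: ``cmap`` (64 color bands, 8 hue progressions of 8
steps, preserving the sense of lightness order), and the ``3-3-2 RGB``
bit-partition table (256 distinct entries, four times more bands, which
maximizes gradient visibility at the cost of lightness order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import LogMappedImage, LogRange

__all__ = [
    "PseudocolorLut",
    "cmap_lut",
    "rgb332_lut",
    "apply_lut",
    "make_colorbar",
    "superposition",
]


@dataclass(frozen=True)
class PseudocolorLut:
    """256-entry RGB lookup table."""

    name: str
    entries: np.ndarray = field(repr=False)  # (256, 3) uint8

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if e.shape != (256, 3):
            raise ValueError(f"LUT must have exactly 256 RGB entries, got shape {e.shape}")
        object.__setattr__(self, "entries", e.astype(np.uint8))

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "PseudocolorLut":
        """Load a table from CSV with columns ``index,r,g,b`` (256 rows)."""
        df = pd.read_csv(path)
        missing = {"index", "r", "g", "b"} - set(df.columns)
        if missing:
            raise ValueError(f"LUT CSV needs columns index,r,g,b (missing {sorted(missing)})")
        df = df.sort_values("index")
        if len(df) != 256 or list(df["index"]) != list(range(256)):
            raise ValueError("LUT CSV must contain exactly the indices 0..255")
        return cls(name=name or Path(path).stem, entries=df[["r", "g", "b"]].to_numpy())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.entries, columns=["r", "g", "b"])
        df.insert(0, "index", np.arange(256))
        df.to_csv(path, index=False)


def band_index(digit) -> np.ndarray:
    """cmap band for a digit: 64 bands, each spanning 4 consecutive digits.

    ``band = clip(round(digit/4), 0, 63)`` with ties rounding away from
    zero, so digits 194-197 share band 49.
    """
    d = np.asarray(digit, dtype=np.float64)
    return np.clip(np.floor(d / 4.0 + 0.5), 0, 63).astype(np.intp)


# 8 hue progressions, each a linear ramp between two anchor colors over 8
# steps.  Progression 6 is pinned so its step 1 (band 49, digits 194-197)
# is exactly the green triplet [192, 255, 64]; the published table of the
# remaining 63 bands is not printed anywhere, so the rest are this
# package's own ramps ordered dark-to-bright (replace via from_csv to
# match any external table exactly).
_CMAP_PROGRESSIONS = (
    ((0, 0, 48), (0, 0, 255)),        # deep blues
    ((64, 0, 128), (160, 64, 255)),   # purples
    ((128, 0, 0), (255, 64, 32)),     # reds
    ((128, 64, 0), (255, 160, 0)),    # oranges
    ((0, 64, 64), (0, 192, 192)),     # teals
    ((0, 96, 0), (64, 224, 32)),      # greens
    ((183, 255, 57), (246, 255, 106)),  # yellow-greens; step 1 = [192,255,64]
    ((224, 224, 224), (255, 255, 255)),  # whites
)


def cmap_lut() -> PseudocolorLut:
    """The 64-band analysis LUT (8 progressions x 8 steps)."""
    entries = np.empty((256, 3), np.uint8)
    bands = band_index(np.arange(256))
    for b in range(64):
        p, s = divmod(b, 8)
        a, z = np.array(_CMAP_PROGRESSIONS[p], float)
        color = np.floor(a + (z - a) * s / 7.0 + 0.5).astype(np.uint8)
        entries[bands == b] = color
    return PseudocolorLut(name="cmap", entries=entries)


def rgb332_lut() -> PseudocolorLut:
    """The 3-3-2 RGB bit-partition LUT.

    Red takes the top 3 bits of the digit, green the next 3, blue the low
    2, each left-shifted into an 8-bit channel.  Entry 0 is black; entry
    255 is the maximal yellow-tinted entry (blue tops out at 192).
    """
    d = np.arange(256)
    entries = np.stack(
        [(d >> 5) << 5, ((d >> 2) & 0b111) << 5, (d & 0b11) << 6], axis=1
    )
    return PseudocolorLut(name="3-3-2 RGB", entries=entries)


def apply_lut(image, lut: PseudocolorLut) -> np.ndarray:
    """Per-pixel table lookup of an 8-bit image: returns (H, W, 3) uint8."""
    digits = np.asarray(getattr(image, "digits", image))
    if digits.dtype != np.uint8:
        raise ValueError(f"apply_lut needs 8-bit digits, got {digits.dtype}")
    return lut.entries[digits]


def make_colorbar(lut: PseudocolorLut, log_range: LogRange = LogRange(), *,
                  width: int = 32, n_ticks: int = 6):
    """Vertical color bar of all 256 entries with log-luminance ticks.

    Returns ``(rgb, ticks)``: an RGB image with entry 255 (log 0.0) at
    the top and entry 0 (log -range) at the bottom, one row per entry,
    and a list of ``(row, log10_value)`` tick annotations.
    """
    col = lut.entries[::-1]  # top row = entry 255
    rgb = np.repeat(col[:, None, :], width, axis=1)
    ticks = []
    for i in range(n_ticks):
        frac = i / (n_ticks - 1)
        row = int(round(frac * 255))
        ticks.append((row, -log_range.range_log10 * frac))
    return rgb, ticks


def superposition(quadrant_images, boundary_mask: np.ndarray) -> np.ndarray:
    """Composite of four quarter-image sections plus a red boundary trace.

    ``quadrant_images`` supplies, in order, the sources of the top-left,
    top-right, bottom-right and bottom-left quadrants; all four must
    share one (H, W, 3) shape.  Pixels of ``boundary_mask`` are painted
    pure red, locating (for example) a scene's max/min edge inside the
    smooth post-glare gradients.
    """
    imgs = [np.asarray(im) for im in quadrant_images]
    if len(imgs) != 4:
        raise ValueError(f"need exactly four quadrant images, got {len(imgs)}")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs) or np.asarray(boundary_mask).shape != shape[:2]:
        raise ValueError("quadrant images and mask must all share one shape")
    h, w = shape[0], shape[1]
    out = np.empty(shape, np.uint8)
    tl, tr, br, bl = imgs
    out[: h // 2, : w // 2] = tl[: h // 2, : w // 2]
    out[: h // 2, w // 2 :] = tr[: h // 2, w // 2 :]
    out[h // 2 :, w // 2 :] = br[h // 2 :, w // 2 :]
    out[h // 2 :, : w // 2] = bl[h // 2 :, : w // 2]
    out[np.asarray(boundary_mask, bool)] = (255, 0, 0)
    return out
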