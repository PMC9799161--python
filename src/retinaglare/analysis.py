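"""Quantifying glare's redistribution of light.

Glare is nearly invisible by inspection, so its effects are measured:
ROI statistics in log10 and percent-of-log-range conventions, global
dynamic ranges, 256-bin histograms normalized to their own peak,
one-pixel scan-line profiles, and the Glare's-Paradox report -- whether
the ROI that *appears* darker in fact receives more light on the retina.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mapping import LogRange, percent_of_range
from .targets import TargetBundle

__all__ = [
    "RoiStats",
    "HistogramResult",
    "ScanProfile",
    "ParadoxReport",
    "roi_stats",
    "image_range",
    "histogram",
    "scan",
    "paradox_report",
]


def _values_of(image) -> np.ndarray:
    return np.asarray(getattr(image, "values", image), dtype=np.float64)


@dataclass(frozen=True)
class RoiStats:
    """Min/max/mean of one ROI, in log10-relative and percent conventions."""

    roi_name: str
    n_pixels: int
    erosion_px: int
    log10_min: float
    log10_max: float
    log10_mean: float
    percent_min: float
    percent_max: float
    percent_mean: float
    linear_mean: float


def roi_stats(image, mask: np.ndarray, log_range: LogRange = LogRange(), *,
              roi_name: str = "roi", erosion_px: int = 2) -> RoiStats:
    """Statistics of an image over a binary ROI mask.

    The mask is eroded by ``erosion_px`` pixels first (the outermost one
    or two pixels of a segment carry extreme edge-gradient values that do
    not describe the region); pass ``erosion_px=0`` for full-mask stats.
    If erosion would empty the mask, the full mask is used.
    """
    v = _values_of(image)
    mask = np.asarray(mask, bool)
    if mask.shape != v.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {v.shape}")
    if not mask.any():
        raise ValueError(f"ROI {roi_name!r}: empty mask")
    if erosion_px > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erosion_px)
        if eroded.any():
            mask = eroded
        else:
            erosion_px = 0
    sel = v[mask]
    vmax = v.max()
    logs = np.log10(sel / vmax)
    pcts = percent_of_range(sel, vmax, log_range)
    return RoiStats(
        roi_name=roi_name,
        n_pixels=int(mask.sum()),
        erosion_px=erosion_px,
        log10_min=float(logs.min()),
        log10_max=float(logs.max()),
        log10_mean=float(logs.mean()),
        percent_min=float(np.min(pcts)),
        percent_max=float(np.max(pcts)),
        percent_mean=float(np.mean(pcts)),
        linear_mean=float(sel.mean()),
    )


def image_range(image, log_range: LogRange = LogRange()) -> float:
    """Global log10(max/min) of a positive image, as percent of ``log_range``."""
    v = _values_of(image)
    if not v.min() > 0:
        raise ValueError("image_range needs a strictly positive image")
    span = float(np.log10(v.max() / v.min()))
    return float(np.clip(100.0 * span / log_range.range_log10, 0.0, 100.0))


@dataclass(frozen=True)
class HistogramResult:
    """256-bin histogram, counts normalized to the histogram's own peak."""

    mode: str  # 'linear' or 'log'
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    @property
    def normalized_counts(self) -> np.ndarray:
        peak = self.counts.max()
        return self.counts / peak if peak > 0 else self.counts.astype(float)


def histogram(image, mode: str = "log", log_range: LogRange = LogRange()) -> HistogramResult:
    """256-bin histogram of a positive image.

    ``linear`` mode bins the linear values over [0, max]; ``log`` mode
    bins log10(v/max) over [-range, 0], with values below the floor
    clipped into the lowest bin.
    """
    if mode not in ("linear", "log"):
        raise ValueError(f"mode must be 'linear' or 'log', got {mode!r}")
    v = _values_of(image)
    if mode == "linear":
        edges = np.linspace(0.0, v.max(), 257)
        counts, _ = np.histogram(v, bins=edges)
    else:
        logs = np.log10(np.maximum(v, 1e-300) / v.max())
        logs = np.clip(logs, -log_range.range_log10, 0.0)
        edges = np.linspace(-log_range.range_log10, 0.0, 257)
        counts, _ = np.histogram(logs, bins=edges)
    return HistogramResult(mode=mode, bin_edges=edges, counts=counts)


@dataclass(frozen=True)
class ScanProfile:
    """Paired one-pixel-high horizontal profiles of scene and retina."""

    row: int
    scene_log10: np.ndarray = field(repr=False)
    retina_log10: np.ndarray = field(repr=False)

    @property
    def scene_span(self) -> float:
        return float(self.scene_log10.max() - self.scene_log10.min())

    @property
    def retina_span(self) -> float:
        return float(self.retina_log10.max() - self.retina_log10.min())


def scan(scene, retina, row: int) -> ScanProfile:
    """Log10-relative profiles of scene and retina along one pixel row."""
    sv, rv = _values_of(scene), _values_of(retina)
    if sv.shape != rv.shape:
        raise ValueError("scene and retina shapes differ")
    if not 0 <= row < sv.shape[0]:
        raise ValueError(f"row {row} out of range for image with {sv.shape[0]} rows")
    return ScanProfile(
        row=row,
        scene_log10=np.log10(sv[row] / sv.max()),
        retina_log10=np.log10(rv[row] / rv.max()),
    )


@dataclass(frozen=True)
class ParadoxReport:
    """Glare's Paradox verdict for one declared appearance pair.

    ``paradox`` is true when the ROI declared to *appear darker* in fact
    has the higher mean retinal contrast -- i.e. neural processing not
    only cancels the extra glare light but overcompensates it.
    """

    roi_darker: str
    roi_lighter: str
    mean_darker: float
    mean_lighter: float

    @property
    def paradox(self) -> bool:
        return self.mean_darker > self.mean_lighter


def paradox_report(retina, bundle: TargetBundle, *, erosion_px: int = 2) -> list[ParadoxReport]:
    """One :class:`ParadoxReport` per declared appearance pair of a bundle."""
    reports = []
    for darker, lighter in bundle.appearance_order:
        for name in (darker, lighter):
            if name not in bundle.rois:
                raise KeyError(f"ROI {name!r} declared in appearance_order but missing from bundle")
        sd = roi_stats(retina, bundle.rois[darker], roi_name=darker, erosion_px=erosion_px)
        sl = roi_stats(retina, bundle.rois[lighter], roi_name=lighter, erosion_px=erosion_px)
        reports.append(
            ParadoxReport(
                roi_darker=darker,
                roi_lighter=lighter,
                mean_darker=sd.linear_mean,
                mean_lighter=sl.linear_mean,
            )
        )
    return reports
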