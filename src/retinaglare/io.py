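"""File output helpers: float TIFFs with JSON sidecars, PNGs, checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


def save_float_tiff(values: np.ndarray, path, sidecar: dict | None = None) -> Path:
    """Write a 64-bit float TIFF; optionally a ``<path>.json`` sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(values, np.float64))
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def save_png(array: np.ndarray, path) -> Path:
    """Write an 8-bit grayscale or RGB PNG."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, np.asarray(array, np.uint8))
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
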