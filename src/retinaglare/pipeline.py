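"""End-to-end run: generate/load -> calibrate -> convolve -> map -> report.

One :func:`run` call reproduces the full eight-image analysis set for a
stimulus -- the digit map, its display rendering, the linear scene
luminance and retinal contrast arrays, both log-mapped grayscales and
both pseudocolor renderings -- plus the ROI statistics, histogram and
Glare's-Paradox CSV reports, all listed in a manifest with parameter
provenance and checksums.  Runs are deterministic given a config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, targets
from .calibration import DisplayCalibration, apply_calibration, load_digit_map
from .convolve import PaddingMode, convolve
from .gsf import AngularGeometry, GlareParameters, get_kernel
from .io import save_float_tiff, save_png, sha256_of
from .mapping import LogRange, log_map
from .pseudocolor import apply_lut, cmap_lut, rgb332_lut

__all__ = ["RunConfig", "run", "ConfigError", "StageError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Either ``target`` names a built-in generator (``contrast_A`` ..
    ``contrast_D``, ``todorovic``, ``centered_square``, ``mondrian``,
    with ``_negative`` suffix for the Mondrian inverse), or ``image`` and
    ``calibration`` point to a user-supplied digit map and calibration
    CSV.  All defaults match the reproduction conditions: age 25,
    pigment 0.5, replicate padding, log range 2.3.
    """

    target: str | None = None
    image: str | None = None
    calibration: str | None = None
    field_of_view_deg: float | None = None  # required for user images
    age: float = 25.0
    pigment: float = 0.5
    padding: str = "replicate"
    padding_value: float = 0.0
    log_range: float = 2.3
    lut: str = "cmap"
    size: int | None = None
    seed: int = 0
    out_dir: str = "retinaglare_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.target is None) == (self.image is None):
            raise ConfigError("config must set exactly one of 'target' or 'image'")
        if self.image is not None and self.calibration is None:
            raise ConfigError("a user image needs a 'calibration' CSV")
        if self.image is not None and self.field_of_view_deg is None:
            raise ConfigError("a user image needs 'field_of_view_deg'")
        if self.lut not in ("cmap", "3-3-2"):
            raise ConfigError(f"lut must be 'cmap' or '3-3-2', got {self.lut!r}")


def _load_bundle(cfg: RunConfig) -> targets.TargetBundle:
    name = cfg.target
    if name is None:
        digit_map = load_digit_map(cfg.image)
        cal = DisplayCalibration.from_csv(cfg.calibration)
        return targets.TargetBundle(
            map=digit_map,
            calibration=cal,
            rois={},
            appearance_order=[],
            geometry=AngularGeometry(digit_map.shape, cfg.field_of_view_deg),
            metadata={"source": str(cfg.image)},
        )
    size = cfg.size
    if name.startswith("contrast_"):
        return targets.make_contrast_assimilation(name.split("_", 1)[1], size or 2048)
    if name == "todorovic":
        return targets.make_todorovic((size, 2 * size) if size else (2048, 4096))
    if name == "centered_square":
        return targets.make_centered_square(size or 2049)
    if name == "mondrian":
        return targets.make_mondrian(cfg.seed, size=size or 2048)
    if name == "mondrian_negative":
        pos = targets.make_mondrian(cfg.seed, size=size or 2048)
        return targets.invert(pos, appearance_order=[("circle_top", "circle_bottom")])
    raise ConfigError(f"unknown target {name!r}")


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except ConfigError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-labelled with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    bundle = _stage("generate")(_load_bundle, config)
    scene = _stage("calibrate")(apply_calibration, bundle.map, bundle.calibration)
    params = GlareParameters(config.age, config.pigment)
    kernel = _stage("kernel")(get_kernel, bundle.geometry, params)
    padding = PaddingMode(config.padding, config.padding_value)
    retina = _stage("convolve")(convolve, scene, kernel, padding)
    lr = LogRange(config.log_range)
    scene_log = log_map(scene, lr)
    retina_log = log_map(retina, lr)
    lut = cmap_lut() if config.lut == "cmap" else rgb332_lut()

    # the eight-image analysis set
    written.append(save_png(bundle.map.digits, out / "map.png"))
    written.append(save_png(bundle.map.digits, out / "display.png"))  # image as displayed
    written.append(
        save_float_tiff(scene.values, out / "scene_luminance.tif",
                        {"max_cd_m2": scene.max_cd_m2, "normalized": True})
    )
    written.append(out / "scene_luminance.tif.json")
    written.append(save_float_tiff(retina.values, out / "retinal_contrast.tif", retina.sidecar()))
    written.append(out / "retinal_contrast.tif.json")
    written.append(save_png(scene_log.digits, out / "scene_luminance_log_mapped.png"))
    written.append(save_png(retina_log.digits, out / "retinal_contrast_log_mapped.png"))
    written.append(save_png(apply_lut(scene_log, lut), out / "scene_luminance_pseudocolor.png"))
    written.append(save_png(apply_lut(retina_log, lut), out / "retinal_contrast_pseudocolor.png"))
    for p in ("scene_luminance_log_mapped", "retinal_contrast_log_mapped"):
        Path(str(out / p) + ".png.json").write_text(json.dumps({"log_range": lr.range_log10}))
        written.append(out / (p + ".png.json"))

    # analysis CSVs
    rows = []
    for img_name, img in (("scene", scene), ("retina", retina)):
        for roi_name, mask in bundle.rois.items():
            for ero in (0, 2):
                st = analysis.roi_stats(img, mask, lr, roi_name=roi_name, erosion_px=ero)
                rows.append({"image": img_name, **dataclasses.asdict(st)})
    if rows:
        pd.DataFrame(rows).to_csv(out / "roi_stats.csv", index=False)
        written.append(out / "roi_stats.csv")

    hrows = []
    for img_name, img in (("scene", scene), ("retina", retina)):
        for mode in ("linear", "log"):
            h = analysis.histogram(img, mode, lr)
            hrows.append(
                pd.DataFrame({
                    "image": img_name, "mode": mode,
                    "bin_left": h.bin_edges[:-1], "bin_right": h.bin_edges[1:],
                    "count": h.counts, "normalized": h.normalized_counts,
                })
            )
    pd.concat(hrows).to_csv(out / "histograms.csv", index=False)
    written.append(out / "histograms.csv")

    if bundle.appearance_order:
        reports = analysis.paradox_report(retina, bundle)
        pd.DataFrame(
            [{**dataclasses.asdict(r), "paradox": r.paradox} for r in reports]
        ).to_csv(out / "paradox.csv", index=False)
        written.append(out / "paradox.csv")

    ranges = {
        "scene_percent_of_log_range": analysis.image_range(scene, lr),
        "retina_percent_of_log_range": analysis.image_range(retina, lr),
        "retina_linear_range": float(retina.values.max() / retina.values.min()),
        "energy_ratio": retina.energy_ratio,
    }
    manifest = {
        "config": dataclasses.asdict(config),
        "kernel": kernel.sidecar(),
        "ranges": ranges,
        "metadata": _jsonable(bundle.metadata),
        "files": {p.name: sha256_of(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
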