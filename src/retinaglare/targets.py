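"""Generators for the lightness-illusion stimuli and their metadata.

Every generated target is a :class:`TargetBundle`: the 8-bit digit map,
the display calibration that turns it into luminances, named binary ROI
masks for the equal-luminance gray segments, and the declared appearance
ordering of each ROI pair (which member *looks* darker).  The bundle is
everything downstream analysis needs, so the whole pipeline is testable
without any external artwork.

The published stimuli exist only as figures; the generators reconstruct
them parametrically so that every printed constraint holds: the three
display luminances (White 450, Gray 136, Black 2.24 cd/m^2, a 200:1
range), the area fractions of the Contrast+Assimilation targets (Gray 14%
everywhere; White/Black 57%/29% for variants A and B, 29%/57% for C and
D), the outer-band colors, the relative surround sizes (A larger than B,
C larger than D), and the Todorovic cross dimensions (arms 380 x 25
pixels, gray circles 46 arcmin from the nearest max/min edge).  A small
fixed-point solver adjusts the free dimensions (surround side, test-bar
length, one balancing band) so the printed area fractions are met at any
generation size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    DigitMap,
    DisplayCalibration,
    SceneLuminance,
    apply_calibration,
    default_display_calibration,
)
from .gsf import AngularGeometry

__all__ = [
    "TargetBundle",
    "make_contrast_assimilation",
    "make_todorovic",
    "make_centered_square",
    "make_mondrian",
    "invert",
]

WHITE, GRAY, BLACK = 255, 145, 21

#: fraction of total pixels each digit class must occupy (Contrast+Assimilation)
GRAY_FRACTION = 0.14
MAJOR_FRACTION = 0.57  # White in A/B, Black in C/D
MINOR_FRACTION = 0.29

AREA_TOL = 0.01  # printed fractions must hold within 1% of total pixels


@dataclass
class TargetBundle:
    """A generated stimulus with everything needed to analyze it."""

    map: DigitMap
    calibration: DisplayCalibration
    rois: dict[str, np.ndarray]
    appearance_order: list[tuple[str, str]]  # (roi_darker, roi_lighter)
    geometry: AngularGeometry
    metadata: dict

    def scene_luminance(self) -> SceneLuminance:
        return apply_calibration(self.map, self.calibration)

    def digit_fractions(self) -> dict[int, float]:
        d = self.map.digits
        vals, counts = np.unique(d, return_counts=True)
        return {int(v): float(c) / d.size for v, c in zip(vals, counts)}


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# Contrast + Assimilation, variants A-D
# ---------------------------------------------------------------------------

# base-layout coordinates at the reference size 2048 (scaled for other sizes)
_CA_BASE = {
    "band": 40,          # outer band width (White for A/B, Black for C/D)
    "sep": (948, 1048),  # gray separator rows between the two illusions
    "stripe_block": (1048, 2008),  # gray-bordered block holding the stripes
    "stripe_rows": (1080, 1976),   # 14 pairs of (white 40 + black 24) rows
    "stripe_cols": (72, 1976),
    "pair_pitch": 64,
    "white_h": 40,
    "black_h": 24,
    "row_c": 493,        # contrast-half row center
    "col_left": 560,     # gray-in-white ROI column center
    "col_right": 1270,   # gray-in-black ROI column center
    "roi_h": 160,
    "roi_w": 240,
    "bar_left_col": 200,   # bars on white stripes (flanked by black)
    "bar_right_col": 1100,  # bars on black stripes (flanked by white)
    "white_pairs": (3, 6, 9, 12),
    "black_pairs": (4, 7, 10, 13),
}


def _ca_build(variant: str, n: int, s: int, bar_len: int, comp_h: int) -> np.ndarray:
    q = n / 2048.0
    sc = lambda x: int(round(x * q))
    b = _CA_BASE
    band = WHITE if variant in "AB" else BLACK
    m = np.full((n, n), band, np.uint8)

    m[sc(948) : sc(1048), sc(40) : n - sc(40)] = GRAY          # separator
    m[sc(1048) : sc(2008), sc(40) : n - sc(40)] = GRAY         # stripe block border
    r0, c0, c1 = sc(1080), sc(72), sc(1976)
    hw, hb = sc(40), sc(24)
    r = r0
    for _ in range(14):
        m[r : r + hw, c0:c1] = WHITE
        m[r + hw : r + hw + hb, c0:c1] = BLACK
        r += hw + hb

    row_c = sc(b["row_c"])
    if variant in "AB":
        cc = sc(b["col_right"])
        m[row_c - s // 2 : row_c - s // 2 + s, cc - s // 2 : cc - s // 2 + s] = BLACK
        if variant == "B":  # balancing band: black, along the top
            m[sc(40) : sc(40) + comp_h, sc(40) : n - sc(40)] = BLACK
    else:
        cc = sc(b["col_left"])
        m[row_c - s // 2 : row_c - s // 2 + s, cc - s // 2 : cc - s // 2 + s] = WHITE
        if variant == "D":  # balancing band: white, just above the separator
            m[sc(948) - comp_h : sc(948), sc(40) : n - sc(40)] = WHITE

    m[sc(413) : sc(573), sc(440) : sc(680)] = GRAY   # gray-in-white ROI
    m[sc(413) : sc(573), sc(1150) : sc(1390)] = GRAY  # gray-in-black ROI

    for j in b["white_pairs"]:  # bars replacing white-stripe segments
        rr = r0 + sc(64) * j
        m[rr : rr + hw, sc(200) : sc(200) + bar_len] = GRAY
    for j in b["black_pairs"]:  # bars replacing black-stripe segments
        rr = r0 + sc(64) * j + hw
        m[rr : rr + hb, sc(1100) : sc(1100) + bar_len] = GRAY
    return m


def make_contrast_assimilation(variant: str, size: int = 2048) -> TargetBundle:
    """Generate one of the four Contrast+Assimilation targets.

    Top half: the Contrast illusion -- two identical Gray rectangles, one
    in a large uniform White surround, one in Black.  Bottom half: a
    stripe Assimilation illusion -- identical Gray bars replacing stripe
    segments, one group flanked by White stripes, the other by Black.
    Variants: A/B have a White outer band (White 57% of area), C/D a
    Black band (Black 57%); B and D have smaller Contrast surrounds than
    A and C.  Gray segments sit at identical locations in all variants
    and occupy 14% of the area.
    """
    variant = variant.upper()
    if variant not in "ABCD" or len(variant) != 1:
        raise ValueError(f"variant must be one of A, B, C, D, got {variant!r}")
    if size < 512:
        raise ValueError(f"size must be >= 512 to honor area fractions within 1%, got {size}")

    q = size / 2048.0
    total = size * size
    f_white = MAJOR_FRACTION if variant in "AB" else MINOR_FRACTION
    # free dimensions, refined by fixed-point iteration on the pixel counts
    s = int(round({"A": 775, "B": 430, "C": 544, "D": 430}[variant] * q))
    bar_len = int(round(600 * q))
    comp_h = int(round({"A": 0, "B": 216, "C": 0, "D": 58}[variant] * q))
    solve_s = variant in "AC"
    per_bar_rows = 4 * int(round(40 * q)) + 4 * int(round(24 * q))

    m = None
    for _ in range(12):
        m = _ca_build(variant, size, s, bar_len, comp_h)
        fw = np.count_nonzero(m == WHITE) / total
        fg = np.count_nonzero(m == GRAY) / total
        err_w = (fw - f_white) * total
        err_g = (fg - GRAY_FRACTION) * total
        if abs(err_w) < 0.002 * total and abs(err_g) < 0.002 * total:
            break
        bar_len = int(np.clip(bar_len - err_g / max(per_bar_rows, 1), 40 * q, 800 * q))
        if solve_s:
            # white square adds s^2 white (C), black square removes it (A)
            s2 = s * s + (err_w if variant == "A" else -err_w)
            s = int(round(np.sqrt(max(s2, 100))))
        else:
            width = size - 2 * int(round(40 * q))
            dh = err_w / width
            comp_h = int(np.clip(comp_h + (dh if variant == "B" else -dh), 0, 360 * q))

    fracs = {
        "white": np.count_nonzero(m == WHITE) / total,
        "gray": np.count_nonzero(m == GRAY) / total,
        "black": np.count_nonzero(m == BLACK) / total,
    }
    f_black = MINOR_FRACTION if variant in "AB" else MAJOR_FRACTION
    for name, want in (("white", f_white), ("gray", GRAY_FRACTION), ("black", f_black)):
        if abs(fracs[name] - want) > AREA_TOL:
            raise ValueError(
                f"size {size} too small to honor the {name} area fraction within 1% "
                f"(got {fracs[name]:.3f}, want {want:.2f})"
            )

    sc = lambda x: int(round(x * q))
    shape = (size, size)
    rois: dict[str, np.ndarray] = {}
    for name, (cols) in (
        ("gray_in_white_contrast", (sc(440), sc(680))),
        ("gray_in_black_contrast", (sc(1150), sc(1390))),
    ):
        mask = np.zeros(shape, bool)
        mask[sc(413) : sc(573), cols[0] : cols[1]] = True
        rois[name] = mask
    hw, hb, r0 = sc(40), sc(24), sc(1080)
    mask = np.zeros(shape, bool)
    for j in _CA_BASE["white_pairs"]:
        rr = r0 + sc(64) * j
        mask[rr : rr + hw, sc(200) : sc(200) + bar_len] = True
    rois["gray_in_black_assimilation"] = mask  # flanked by black stripes
    mask = np.zeros(shape, bool)
    for j in _CA_BASE["black_pairs"]:
        rr = r0 + sc(64) * j + hw
        mask[rr : rr + hb, sc(1100) : sc(1100) + bar_len] = True
    rois["gray_in_white_assimilation"] = mask  # flanked by white stripes
    rois["black_segments"] = m == BLACK

    return TargetBundle(
        map=DigitMap(m),
        calibration=default_display_calibration(),
        rois=rois,
        # Contrast: the gray in the White surround looks darker.
        # Assimilation: the gray flanked by Black stripes looks darker.
        appearance_order=[
            ("gray_in_white_contrast", "gray_in_black_contrast"),
            ("gray_in_black_assimilation", "gray_in_white_assimilation"),
        ],
        geometry=AngularGeometry(shape, field_of_view_deg=10.0),
        metadata={
            "variant": variant,
            "surround_side_px": s,
            "bar_length_px": bar_len,
            "balancing_band_px": comp_h,
            "area_fractions": fracs,
            "digits": {"white": WHITE, "gray": GRAY, "black": BLACK},
        },
    )


# ---------------------------------------------------------------------------
# Todorovic circles and crosses
# ---------------------------------------------------------------------------

TODOROVIC_BG_DIGIT = 128
TODOROVIC_BG_CDM2 = 100.0


def todorovic_calibration() -> DisplayCalibration:
    """Four-luminance calibration: Black 2.24, background 100, Gray 136, White 450."""
    return DisplayCalibration(
        ((BLACK, 2.24), (TODOROVIC_BG_DIGIT, TODOROVIC_BG_CDM2), (GRAY, 136.0), (WHITE, 450.0))
    )


def make_todorovic(size: tuple[int, int] = (2048, 4096)) -> TargetBundle:
    """Generate the Contrast / Todorovic-Assimilation target.

    Eight identical gray segments on a light-gray background: four
    circles along the top row (two controls on the background; two on a
    shared Black|White Contrast panel, each center 46 arcmin from the
    max/min edge) and four crosses along the bottom (two controls; two as
    gray circles seen through 25-pixel slits in White and Black
    foreground panels, so the visible arms are 380 x 25 pixels).
    """
    rows, cols = size
    if cols != 2 * rows:
        raise ValueError(f"Todorovic target needs a 2:1 aspect (cols = 2*rows), got {size}")
    q = rows / 2048.0
    if round(25 * q) < 3 or round(380 * q) < 40:
        raise ValueError(f"size {size} cannot accommodate the 380x25-pixel cross arms")
    sc = lambda x: int(round(x * q))

    bg = TODOROVIC_BG_DIGIT
    m = np.full((rows, cols), bg, np.uint8)
    yy, xx = np.ogrid[:rows, :cols]

    # contrast panel: black and white halves sharing a vertical edge
    half, edge, row_circ = sc(600), sc(2860), sc(512)
    m[row_circ - half // 2 : row_circ + half // 2, edge - half : edge] = BLACK
    m[row_circ - half // 2 : row_circ + half // 2, edge : edge + half] = WHITE

    r_circ = sc(100)
    offset = sc(157)  # 46 arcmin at 0.293 arcmin/pixel
    circle_centers = {
        "circle_control_left": (row_circ, sc(512)),
        "circle_control_right": (row_circ, sc(1536)),
        "circle_in_black": (row_circ, edge - offset),
        "circle_in_white": (row_circ, edge + offset),
    }
    for c in circle_centers.values():
        m[_disk((rows, cols), c, r_circ)] = GRAY

    # Todorovic panels: gray circle behind cross-shaped slits in a foreground
    row_x = sc(1536)
    fg_half = sc(400)
    slit = sc(12)  # half-width; full slit = 25 px at reference size
    r_tod = sc(190)
    cross_centers = {
        "cross_control_left": (row_x, sc(512)),
        "cross_control_right": (row_x, sc(1536)),
        "cross_in_white": (row_x, sc(2560)),
        "cross_in_black": (row_x, sc(3584)),
    }
    rois: dict[str, np.ndarray] = {}
    for name, (cy, cx) in cross_centers.items():
        # half-pixel center: an even circle diameter, so the visible arm
        # bounding box is exactly (2*r_tod) x (2*slit + 1) pixels
        circ = (yy - cy + 0.5) ** 2 + (xx - cx + 0.5) ** 2 <= r_tod**2
        slits = (np.abs(yy - cy) <= slit) | (np.abs(xx - cx) <= slit)
        if name in ("cross_in_white", "cross_in_black"):
            fg = WHITE if name == "cross_in_white" else BLACK
            m[cy - fg_half : cy + fg_half, cx - fg_half : cx + fg_half] = fg
            panel = (np.abs(yy - cy) < fg_half) & (np.abs(xx - cx) < fg_half)
            m[(slits & panel) & ~circ] = bg  # slit shows background beyond the circle
        cross = circ & slits
        m[cross] = GRAY
        rois[name] = cross
    for name, c in circle_centers.items():
        rois[name] = _disk((rows, cols), c, r_circ)

    return TargetBundle(
        map=DigitMap(m),
        calibration=todorovic_calibration(),
        rois=rois,
        # Contrast circles: in-White looks darker.  Todorovic crosses:
        # behind the Black foreground looks darker (assimilation).
        appearance_order=[
            ("circle_in_white", "circle_in_black"),
            ("cross_in_black", "cross_in_white"),
        ],
        geometry=AngularGeometry((rows, cols), field_of_view_deg=20.0),
        metadata={
            "scan_rows": {"circles": row_circ, "crosses": row_x},
            "cross_arm_px": (2 * r_tod, 2 * slit + 1),
            "circle_radius_px": r_circ,
            "max_min_edge_offset_px": offset,
            "background_cd_m2": TODOROVIC_BG_CDM2,
        },
    )


# ---------------------------------------------------------------------------
# Centered square (pseudocolor/LUT demonstration fixture)
# ---------------------------------------------------------------------------

def make_centered_square(field: int = 2049, square: int | None = None) -> TargetBundle:
    """Min-luminance field with a centered max-luminance square.

    Both sizes must be odd so the square centers exactly (the default
    square is 601 at the reference field of 2049, scaled with the field);
    the bundle also carries the one-pixel boundary-ring mask used by the
    superposition composite to locate the max/min edge inside post-glare
    gradients.
    """
    if square is None:
        square = int(round(field * 601 / 2049))
        square += 1 - square % 2  # next odd
    if field % 2 == 0 or square % 2 == 0:
        raise ValueError(f"field and square must both be odd for exact centering, got {field}, {square}")
    if square >= field:
        raise ValueError("square must be smaller than field")
    m = np.full((field, field), BLACK, np.uint8)
    a = (field - square) // 2
    b = a + square
    m[a:b, a:b] = WHITE
    ring = np.zeros((field, field), bool)
    ring[a:b, a] = ring[a:b, b - 1] = True
    ring[a, a:b] = ring[b - 1, a:b] = True
    square_mask = np.zeros((field, field), bool)
    square_mask[a:b, a:b] = True
    return TargetBundle(
        map=DigitMap(m),
        calibration=default_display_calibration(),
        rois={"square": square_mask, "background": ~square_mask, "boundary_ring": ring},
        appearance_order=[],
        geometry=AngularGeometry((field, field), field_of_view_deg=10.0 * field / 2048.0),
        metadata={"field": field, "square": square},
    )


# ---------------------------------------------------------------------------
# Black-and-white Mondrian with an illumination gradient
# ---------------------------------------------------------------------------

MONDRIAN_CIRCLE_DIGIT = 88  # = round(255 * 10**(-0.46 * 2.3/2.3) ...) -> 80% of log range


def mondrian_calibration() -> DisplayCalibration:
    """Linear display for the Mondrian: digit 0 -> 1 cd/m^2, 255 -> 450."""
    return DisplayCalibration(((0, 1.0), (255, 450.0)))


def _guillotine(rng: np.random.Generator, n: int, n_patches: int, min_side: int):
    rects = [(0, 0, n, n)]
    while len(rects) < n_patches:
        areas = np.array([w * h for (_, _, h, w) in rects], float)
        i = int(rng.choice(len(rects), p=areas / areas.sum()))
        y, x, h, w = rects.pop(i)
        if max(h, w) < 2 * min_side:
            rects.append((y, x, h, w))
            if all(max(hh, ww) < 2 * min_side for (_, _, hh, ww) in rects):
                break
            continue
        if h >= w:
            cut = int(rng.integers(min_side, h - min_side + 1))
            rects += [(y, x, cut, w), (y + cut, x, h - cut, w)]
        else:
            cut = int(rng.integers(min_side, w - min_side + 1))
            rects += [(y, x, h, cut), (y, x + cut, h, w - cut)]
    return rects


def make_mondrian(seed: int, n_patches: int = 120, size: int = 2048) -> TargetBundle:
    """Random achromatic Mondrian under a vertical illumination gradient.

    Rectangular matte patches of random reflectance are lit by an
    illumination gradient that is bright at the bottom and dim at the top.
    Two circular ROIs mark papers whose luminances the gradient equates: a
    high-reflectance paper near the top and a low-reflectance paper near
    the bottom are assigned reflectances such that both circle centers
    emit *exactly* the same luminance, at 80% of the 2.3 log-unit range
    (both regions share one display digit, so the equality is exact by
    construction).  The top circle appears near white, the bottom much
    darker, although the light is identical.
    """
    if n_patches < 20:
        raise ValueError(f"need at least 20 patches for a Mondrian, got {n_patches}")
    q = size / 2048.0
    r_circ = int(round(80 * q))
    min_side = max(int(round(56 * q)), 8)
    gamma = 0.65  # log10 units of illumination change over the full height

    rng = np.random.default_rng(seed)
    for attempt in range(20):
        rects = _guillotine(rng, size, n_patches, min_side)
        need = 2.2 * r_circ

        def pick(row_lo, row_hi, want_col):
            best, best_d = None, np.inf
            for (y, x, h, w) in rects:
                cy, cx = y + h / 2, x + w / 2
                if row_lo <= cy <= row_hi and min(h, w) >= need:
                    d = abs(cx - want_col) + abs(cy - (row_lo + row_hi) / 2)
                    if d < best_d:
                        best, best_d = (y, x, h, w), d
            return best

        top = pick(0.10 * size, 0.40 * size, 0.30 * size)
        bot = pick(0.60 * size, 0.90 * size, 0.70 * size)
        if top is not None and bot is not None and top != bot:
            break
        warnings.warn(f"Mondrian attempt {attempt}: no patch large enough for a circle ROI; re-tiling")
    else:
        raise RuntimeError("could not place Mondrian circle ROIs after 20 tilings")

    refl = 10.0 ** rng.uniform(np.log10(0.04), np.log10(0.92), size=len(rects))
    ys = np.arange(size, dtype=np.float64)
    illum = 10.0 ** (gamma * (ys / size - 1.0))  # bright at bottom, max 1

    lum = np.empty((size, size), np.float64)
    for (y, x, h, w), r in zip(rects, refl):
        lum[y : y + h, x : x + w] = r * illum[y : y + h, None]

    # equate the two circle papers at 80% of the log range: digit 88 on a
    # linear display is 10**(-0.46) of max, i.e. 80% of a 2.3 log range
    ctop = (top[0] + top[2] // 2, top[1] + top[3] // 2)
    cbot = (bot[0] + bot[2] // 2, bot[1] + bot[3] // 2)
    lmax = lum.max()
    target_rel = (1.0 + MONDRIAN_CIRCLE_DIGIT / 255.0 * 449.0) / 450.0  # digit 88 luminance fraction
    for (y, x, h, w), cy in ((top, ctop[0]), (bot, cbot[0])):
        r_needed = target_rel * lmax / illum[cy]
        if not 0.02 <= r_needed <= 0.98:
            raise RuntimeError(f"Mondrian gradient tuning infeasible: reflectance {r_needed:.3f} needed")
        lum[y : y + h, x : x + w] = r_needed * illum[y : y + h, None]
    lmax = lum.max()

    digits = np.clip(np.floor(255.0 * lum / lmax + 0.5), 1, 255).astype(np.uint8)
    # both circle centers quantize to the same digit; make the whole ROI
    # disk carry it so the equal-luminance pair is exact at digit level
    rois = {
        "circle_top": _disk((size, size), ctop, r_circ),
        "circle_bottom": _disk((size, size), cbot, r_circ),
    }
    for mask in rois.values():
        digits[mask] = MONDRIAN_CIRCLE_DIGIT

    return TargetBundle(
        map=DigitMap(digits),
        calibration=mondrian_calibration(),
        rois=rois,
        appearance_order=[("circle_bottom", "circle_top")],  # bottom looks darker
        geometry=AngularGeometry((size, size), field_of_view_deg=10.0),
        metadata={
            "seed": seed,
            "n_patches": len(rects),
            "gradient_log10": gamma,
            "circle_digit": MONDRIAN_CIRCLE_DIGIT,
            "circle_centers": {"top": ctop, "bottom": cbot},
        },
    )


# ---------------------------------------------------------------------------
# Image negation
# ---------------------------------------------------------------------------

def invert(bundle: TargetBundle, appearance_order: list[tuple[str, str]] | None = None) -> TargetBundle:
    """Photographic negative of a target: digits become 255 - digits.

    The calibration and ROI masks are unchanged; the appearance ordering
    cannot be inferred (negated illusions reverse which member looks
    darker in scene-specific ways), so the caller re-declares it.  The
    bundle records whether equal-luminance ROI pairs survive negation --
    they do exactly when the calibration is linear in digits.
    """
    neg = DigitMap(255 - bundle.map.digits)
    meta = dict(bundle.metadata)
    meta["inverted"] = not meta.get("inverted", False)
    pairs_equal = {}
    for a, b in bundle.appearance_order:
        if a in bundle.rois and b in bundle.rois:
            la = bundle.calibration.luminance(neg.digits[bundle.rois[a]])
            lb = bundle.calibration.luminance(neg.digits[bundle.rois[b]])
            pairs_equal[f"{a}|{b}"] = bool(np.isclose(la.mean(), lb.mean(), rtol=1e-12))
    meta["equal_luminance_after_inversion"] = pairs_equal
    return TargetBundle(
        map=neg,
        calibration=bundle.calibration,
        rois=bundle.rois,
        appearance_order=list(appearance_order) if appearance_order else [],
        geometry=bundle.geometry,
        metadata=meta,
    )
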