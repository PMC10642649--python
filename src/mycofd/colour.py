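"""Red-pigment quantification in drop regions.

The RGB scene is converted to CIELAB; the a* plane (green-negative /
red-positive axis) is encoded to 8 bits with the neutral axis at 128.  A
single Huang threshold per image separates pigmented from unpigmented
pixels, optionally small connected components are discarded, and the red
coverage of each polygonal drop region is reported as a percentage of the
region's pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from skimage.measure import label as _cc_label

from .io_roi import PolygonROI, polygon_pixel_mask
from .preprocess import huang_threshold

__all__ = ["DropColourResult", "rgb_to_lab8", "quantify_red_in_drops"]

#: encoded a* value of the neutral (a* = 0) axis
A_NEUTRAL = 128


@dataclass(frozen=True)
class DropColourResult:
    drop_id: int
    roi: PolygonROI
    red_pixels: int
    roi_pixels: int
    percent_red: float
    threshold_used: int
    excluded: bool = False


def rgb_to_lab8(image: np.ndarray) -> np.ndarray:
    """sRGB (D65) -> CIELAB, encoded to 8 bits per plane.

    L* is scaled from [0, 100] to [0, 255]; a* and b* are offset by +128
    and clipped, so 128 on the a-plane is the neutral axis and red pigment
    lands strictly above it.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("rgb_to_lab8 expects an (H, W, 3) RGB image")
    lab = rgb2lab(img)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * 255.0 / 100.0
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return np.floor(np.clip(out, 0.0, 255.0) + 0.5).astype(np.uint8)


def quantify_red_in_drops(
    image: np.ndarray,
    drops: list[PolygonROI],
    min_particle_px: int = 0,
    fixed_threshold: int | None = None,
) -> list[DropColourResult]:
    """Percent red coverage inside each drop polygon.

    One threshold is computed per image (Huang, on the whole a-plane
    histogram) and applied to every drop.  A pixel counts as red when its
    encoded a* exceeds both the threshold and the neutral value 128 — red
    pigment has strictly positive a*, so an automatic threshold that falls
    in the green half-axis can never promote unpigmented pixels to "red".
    Connected components (8-connectivity) smaller than ``min_particle_px``
    are discarded.  Drops not fully inside the image are flagged
    ``excluded`` with zero counts instead of being silently dropped.
    """
    if not drops:
        raise ValueError("need at least one drop ROI")
    if min_particle_px < 0:
        raise ValueError("min_particle_px must be >= 0")
    a_plane = rgb_to_lab8(image)[..., 1]
    if fixed_threshold is not None:
        thr = int(fixed_threshold)
    else:
        thr = huang_threshold(a_plane)
    red = a_plane > max(thr, A_NEUTRAL)
    if min_particle_px > 1 and red.any():
        labels = _cc_label(red, connectivity=2)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_particle_px
        keep[0] = False
        red = keep[labels]

    H, W = a_plane.shape
    results: list[DropColourResult] = []
    for i, roi in enumerate(drops):
        x0, y0, x1, y1 = roi.bounds()
        if x0 < 0 or y0 < 0 or x1 > W - 1 or y1 > H - 1:
            results.append(DropColourResult(i, roi, 0, 0, float("nan"), thr, excluded=True))
            continue
        m = polygon_pixel_mask(roi, (H, W))
        roi_px = int(m.sum())
        red_px = int((red & m).sum())
        pct = 100.0 * red_px / roi_px if roi_px else float("nan")
        results.append(DropColourResult(i, roi, red_px, roi_px, pct, thr))
    return results
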