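"""Raster I/O, regions of interest, and physical-scale area measurement.

Conventions used throughout the package:

* images are numpy arrays, row-major, origin at the top-left;
* coordinates are 0-based with ``x`` = column and ``y`` = row;
* grayscale images are ``(H, W) uint8``, RGB images ``(H, W, 3) uint8``,
  binary masks ``(H, W) bool``;
* a pixel belongs to a polygon when its centre lies inside or on the
  boundary (even–odd rule, boundary-inclusive), so pixel counts are
  bit-stable across runs.

ROIs are stored declaratively in JSON sidecars rather than drawn by hand:
``{"rects": [{"top":..,"left":..,"height":..,"width":..}],
"polygons": [[[x,y], ...], ...], "scale_px_per_cm": float}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
import tifffile

__all__ = [
    "RectROI",
    "PolygonROI",
    "PixelScale",
    "read_image",
    "write_image",
    "crop_rect",
    "polygon_pixel_mask",
    "mask_out_polygons",
    "polygon_area_px",
    "area_cm2",
    "load_roi_sidecar",
    "save_roi_sidecar",
]


@dataclass(frozen=True)
class RectROI:
    """Half-open axis-aligned rectangle [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def validate(self, shape: tuple[int, int]) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("RectROI must have positive size")
        if self.top < 0 or self.left < 0:
            raise ValueError("RectROI must lie inside the image")
        if self.top + self.height > shape[0] or self.left + self.width > shape[1]:
            raise ValueError("RectROI exceeds image bounds")


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon given as an ordered (x, y) vertex list, implicitly closed."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("PolygonROI needs at least 3 vertices")

    def to_shapely(self) -> shapely.Polygon:
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("degenerate or self-intersecting polygon")
        return poly

    def bounds(self) -> tuple[float, float, float, float]:
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass(frozen=True)
class PixelScale:
    """Physical calibration: pixels per centimetre."""

    px_per_cm: float

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


# ---------------------------------------------------------------------------
# raster I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as uint8 gray (H, W) or RGB (H, W, 3).

    Inputs deeper than 8 bits are linearly rescaled so that the image
    minimum maps to 0 and the maximum to 255, with a warning — every
    downstream procedure is defined on 8-bit data.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError(f"unsupported image layout {arr.shape} in {path.name}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"unsupported pixel type {arr.dtype} in {path.name}")
        warnings.warn(
            f"{path.name}: {arr.dtype} input rescaled to 8-bit (min->0, max->255)",
            stacklevel=2,
        )
        lo, hi = int(arr.min()), int(arr.max())
        if hi == lo:
            arr = np.zeros_like(arr, dtype=np.uint8)
        else:
            arr = np.floor((arr.astype(np.float64) - lo) * 255.0 / (hi - lo) + 0.5).astype(np.uint8)
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit gray/RGB image or a boolean mask (as 0/255) losslessly."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise ValueError("write_image expects uint8 or bool data")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# ROI application


def crop_rect(image: np.ndarray, roi: RectROI) -> np.ndarray:
    roi.validate(image.shape[:2])
    return image[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width].copy()


def polygon_pixel_mask(roi: PolygonROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside/on the polygon."""
    poly = roi.to_shapely()
    H, W = shape
    x0, y0, x1, y1 = roi.bounds()
    c0 = max(int(np.floor(x0)), 0)
    c1 = min(int(np.ceil(x1)), W - 1)
    r0 = max(int(np.floor(y0)), 0)
    r1 = min(int(np.ceil(y1)), H - 1)
    mask = np.zeros((H, W), dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    xs, ys = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts).reshape(xs.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def mask_out_polygons(
    image: np.ndarray, rois: list[PolygonROI], fill: int = 0
) -> np.ndarray:
    """Set pixels inside any of the polygons to ``fill``; others untouched."""
    if not 0 <= int(fill) <= 255:
        raise ValueError("fill must be an 8-bit value")
    out = image.copy()
    for roi in rois:
        m = polygon_pixel_mask(roi, image.shape[:2])
        out[m] = fill
    return out


def polygon_area_px(roi: PolygonROI) -> int:
    """Number of pixel centres inside the polygon (boundary-inclusive)."""
    x0, y0, x1, y1 = roi.bounds()
    H = int(np.ceil(y1)) + 1
    W = int(np.ceil(x1)) + 1
    if x0 < 0 or y0 < 0:
        raise ValueError("polygon_area_px expects non-negative coordinates")
    return int(polygon_pixel_mask(roi, (H, W)).sum())


def area_cm2(pixel_count: int, scale: PixelScale) -> float:
    """Convert a pixel count to cm^2 given the calibration."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    return pixel_count / scale.px_per_cm**2


# ---------------------------------------------------------------------------
# ROI sidecar JSON


def load_roi_sidecar(path: str | Path) -> dict:
    """Load an ROI sidecar; returns dict with RectROI/PolygonROI objects."""
    with open(path) as fh:
        raw = json.load(fh)
    rects = [RectROI(**r) for r in raw.get("rects", [])]
    polys = [PolygonROI(tuple((float(x), float(y)) for x, y in p)) for p in raw.get("polygons", [])]
    out = {"rects": rects, "polygons": polys}
    if "scale_px_per_cm" in raw and raw["scale_px_per_cm"] is not None:
        out["scale"] = PixelScale(float(raw["scale_px_per_cm"]))
    return out


def save_roi_sidecar(
    path: str | Path,
    rects: list[RectROI] = (),
    polygons: list[PolygonROI] = (),
    scale: PixelScale | None = None,
) -> None:
    doc = {
        "rects": [vars(r) for r in rects],
        "polygons": [[[float(x), float(y)] for x, y in p.vertices] for p in polygons],
        "scale_px_per_cm": scale.px_per_cm if scale is not None else None,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
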