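"""Edge-preserving smoothing, edge detection and binarization.

The chain ``kuwahara -> sobel_magnitude -> compute_threshold -> binarize``
turns a grayscale micrograph of hyphae into the binary mask consumed by
box counting.  All filters work in float64 internally, use replicate
padding at the borders (no spurious edges that would inflate box counts),
and quantize back to 8-bit with half-away-from-zero rounding only at the
module boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_isodata, threshold_otsu

__all__ = [
    "KuwaharaConfig",
    "ThresholdMethod",
    "kuwahara",
    "sobel_magnitude",
    "huang_threshold",
    "compute_threshold",
    "binarize",
]


@dataclass(frozen=True)
class KuwaharaConfig:
    """Kuwahara filter settings.

    variant
        ``"classic"`` uses the four overlapping square quadrant subwindows
        of a ``window``-sided neighbourhood; ``"linear"`` uses
        ``n_orientations`` line segments of length ``window`` through the
        pixel at angles ``k*pi/n_orientations`` — the oriented variant is
        well suited to thin filaments.
    """

    variant: str = "linear"
    window: int = 5
    n_orientations: int = 8

    def validate(self) -> None:
        if self.variant not in ("classic", "linear"):
            raise ValueError("variant must be 'classic' or 'linear'")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.variant == "linear" and self.n_orientations < 4:
            raise ValueError("n_orientations must be >= 4")


@dataclass(frozen=True)
class ThresholdMethod:
    name: str = "isodata"  # isodata | otsu | huang | fixed
    fixed_value: int | None = None

    def validate(self) -> None:
        if self.name not in ("isodata", "otsu", "huang", "fixed"):
            raise ValueError(f"unknown threshold method {self.name!r}")
        if self.name == "fixed":
            if self.fixed_value is None or not 0 <= self.fixed_value <= 255:
                raise ValueError("fixed threshold requires an 8-bit fixed_value")


def _to_u8(arr: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(arr, 0.0, 255.0) + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Kuwahara


def kuwahara(image: np.ndarray, cfg: KuwaharaConfig = KuwaharaConfig()) -> np.ndarray:
    """Edge-preserving smoothing: each pixel takes the mean of its
    minimum-variance local subwindow (ties broken by lowest region index).

    Because every output value is the mean of a subset of input values,
    the output range never exceeds the input range and step edges are not
    blurred: some subwindow always lies entirely on one side of an edge.
    """
    cfg.validate()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("kuwahara expects a 2D grayscale image")
    if min(img.shape) <= cfg.window:
        raise ValueError("window larger than image")
    if cfg.variant == "classic":
        means, variances = _classic_regions(img, cfg.window)
    else:
        means, variances = _linear_regions(img, cfg.window, cfg.n_orientations)
    choice = np.argmin(variances, axis=0)  # argmin -> lowest index on ties
    out = np.take_along_axis(means, choice[np.newaxis], axis=0)[0]
    return _to_u8(out)


def _classic_regions(img: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Means/variances of the four quadrant subwindows of side ceil(w/2).

    Implemented with summed-area tables on a replicate-padded image so the
    even-sided quadrants of e.g. w=7 are handled exactly.
    """
    q = (window + 1) // 2
    H, W = img.shape
    pad = np.pad(img, q, mode="edge")
    means = []
    variances = []
    s1 = _integral(pad)
    s2 = _integral(pad * pad)
    # offsets of the quadrant's top-left corner relative to the pixel
    offsets = [(-q + 1, -q + 1), (-q + 1, 0), (0, -q + 1), (0, 0)]  # NW, NE, SW, SE
    area = q * q
    for dr, dc in offsets:
        top = q + dr  # index into padded array for pixel (0, 0)
        left = q + dc
        sum1 = _box_sum(s1, top, left, q, H, W)
        sum2 = _box_sum(s2, top, left, q, H, W)
        m = sum1 / area
        v = np.maximum(sum2 / area - m * m, 0.0)
        means.append(m)
        variances.append(v)
    return np.stack(means), np.stack(variances)


def _integral(a: np.ndarray) -> np.ndarray:
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=s[1:, 1:])
    return s


def _box_sum(s: np.ndarray, top: int, left: int, q: int, H: int, W: int) -> np.ndarray:
    r0 = np.arange(H) + top
    c0 = np.arange(W) + left
    return (
        s[np.ix_(r0 + q, c0 + q)]
        - s[np.ix_(r0, c0 + q)]
        - s[np.ix_(r0 + q, c0)]
        + s[np.ix_(r0, c0)]
    )


def line_offsets(length: int, angle: float) -> list[tuple[int, int]]:
    """Integer (dy, dx) offsets of a rasterised line segment of ``length``
    pixels centred on the origin at the given angle (duplicates kept, so
    each orientation always weighs ``length`` samples)."""
    half = length // 2
    return [
        (int(round(t * math.sin(angle))), int(round(t * math.cos(angle))))
        for t in range(-half, half + 1)
    ]


def _linear_regions(
    img: np.ndarray, length: int, n_orientations: int
) -> tuple[np.ndarray, np.ndarray]:
    means = []
    variances = []
    half = length // 2
    for k in range(n_orientations):
        angle = k * math.pi / n_orientations
        kernel = np.zeros((2 * half + 1, 2 * half + 1))
        for dy, dx in line_offsets(length, angle):
            kernel[dy + half, dx + half] += 1.0
        kernel /= kernel.sum()
        m = ndimage.correlate(img, kernel, mode="nearest")
        m2 = ndimage.correlate(img * img, kernel, mode="nearest")
        means.append(m)
        variances.append(np.maximum(m2 - m * m, 0.0))
    return np.stack(means), np.stack(variances)


# ---------------------------------------------------------------------------
# Sobel


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude with the standard 3x3 Sobel kernels.

    ``sqrt(Gx^2 + Gy^2)`` clipped to [0, 255] and rounded; borders use
    replicate padding.  Invariant under intensity offsets (before clip).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("sobel_magnitude expects a 2D image of at least 3x3")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    return _to_u8(np.hypot(gx, gy))


# ---------------------------------------------------------------------------
# thresholding


def huang_threshold(image_or_hist: np.ndarray) -> int:
    """Huang & Wang fuzzy threshold of an 8-bit image (or 256-bin histogram).

    For each candidate t, pixels get a membership
    ``mu(g) = 1 / (1 + |g - m(g,t)| / C)`` to their class (class means
    ``m``, ``C`` = full grey-level range of the image), and the Shannon
    fuzziness ``S(t) = -sum h(g) [mu ln mu + (1-mu) ln(1-mu)]`` is
    minimised; ties return the smallest t.  This is the "Huang" method of
    common image-analysis toolboxes.
    """
    arr = np.asarray(image_or_hist)
    if arr.ndim == 1 and arr.size == 256:
        hist = arr.astype(np.float64)
    else:
        hist = np.bincount(arr.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    nz = np.flatnonzero(hist)
    if nz.size == 0:
        raise ValueError("degenerate histogram: empty image")
    gmin, gmax = int(nz[0]), int(nz[-1])
    if gmin == gmax:
        raise ValueError("degenerate histogram: constant image")
    C = float(gmax - gmin)
    g = np.arange(256, dtype=np.float64)
    cum_h = np.cumsum(hist)
    cum_w = np.cumsum(hist * g)

    best_t = gmin
    best_s = np.inf
    for t in range(gmin, gmax):
        h0 = cum_h[t]
        h1 = cum_h[-1] - h0
        mu0 = cum_w[t] / h0
        mu1 = (cum_w[-1] - cum_w[t]) / h1
        mem = np.empty(256)
        mem[: t + 1] = 1.0 / (1.0 + np.abs(g[: t + 1] - mu0) / C)
        mem[t + 1 :] = 1.0 / (1.0 + np.abs(g[t + 1 :] - mu1) / C)
        mu = mem[gmin : gmax + 1]
        hh = hist[gmin : gmax + 1]
        anti = 1.0 - mu
        ent = -(mu * np.log(mu))
        ent -= np.where(anti > 0.0, anti * np.log(np.where(anti > 0.0, anti, 1.0)), 0.0)
        s = float(np.dot(hh, ent))
        if s < best_s - 1e-12:
            best_s = s
            best_t = t
    return int(best_t)


def compute_threshold(image: np.ndarray, method: ThresholdMethod) -> int:
    """Select an 8-bit threshold by the configured method.

    Automatic methods raise on constant images ("degenerate histogram").
    """
    method.validate()
    if method.name == "fixed":
        return int(method.fixed_value)  # type: ignore[arg-type]
    img = np.asarray(image, dtype=np.uint8)
    if img.min() == img.max():
        raise ValueError("degenerate histogram: constant image")
    if method.name == "huang":
        return huang_threshold(img)
    if method.name == "otsu":
        return int(threshold_otsu(img))
    return int(threshold_isodata(img))


def binarize(image: np.ndarray, threshold: int, polarity: str = "above_is_fg") -> np.ndarray:
    """Binary mask from an 8-bit image: foreground = pixel > threshold
    (``above_is_fg``) or its complement (``below_is_fg``)."""
    img = np.asarray(image)
    if polarity == "above_is_fg":
        return img > threshold
    if polarity == "below_is_fg":
        return img <= threshold
    raise ValueError("polarity must be 'above_is_fg' or 'below_is_fg'")
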