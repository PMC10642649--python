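"""Synthetic test-image generators.

Three families of inputs stand in for microscope/camera data so that every
downstream stage can be exercised without any external image:

* :func:`simulate_mycelium` — a 2D tip-growth model producing thin bright
  filaments on a noisy, unevenly illuminated dark background, the kind of
  scene photographed between two media drops colonised by a fungus.
* :func:`render_fractal` — analytic fixtures (line, filled square,
  Sierpinski carpet, random dust) whose box-counting dimension is known in
  closed form, used to validate the fractal-dimension estimator.
* :func:`render_drop_scene` — circular media drops on a bright background
  in which a red pigment occupies an exactly known fraction of the drop
  interior, used to validate the colour-quantification stage.

All generators are pure functions of (parameters, seed): identical inputs
give bit-identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import disk as _disk_px
from skimage.draw import line as _line_px
from skimage.morphology import disk as _disk_footprint

__all__ = [
    "MyceliumParams",
    "FractalFixtureSpec",
    "DropSpec",
    "DropSceneParams",
    "simulate_mycelium",
    "render_fractal",
    "render_drop_scene",
    "theoretical_dimension",
]


@dataclass(frozen=True)
class MyceliumParams:
    """Parameters of the branching tip-growth simulator.

    Defaults emulate a field of view between two drops: a handful of hyphae
    entering from the inoculum side (left edge), advancing a few pixels per
    step with slight heading wander, occasionally branching at a shallow
    angle.  Intensities mimic phase-bright hyphae on a dark background with
    camera noise and a mild lateral illumination gradient.
    """

    seed: int
    width_px: int = 512
    height_px: int = 384
    n_tips0: int = 5
    step_len_px: float = 4.0
    jitter_sd_rad: float = 0.25
    branch_prob: float = 0.05
    branch_angle_rad: float = 0.6
    hypha_width_px: int = 2
    n_steps: int = 100
    max_tips: int = 150
    fg_level: int = 200
    bg_level: int = 30
    noise_sd: float = 8.0
    illum_amp: float = 20.0

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("canvas must be at least 64x64 px")
        if self.n_steps <= 0 or self.n_tips0 <= 0:
            raise ValueError("empty simulation")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if not 0 <= self.bg_level < self.fg_level <= 255:
            raise ValueError("require 0 <= bg_level < fg_level <= 255")
        if self.step_len_px <= 0 or self.hypha_width_px < 1:
            raise ValueError("step_len_px must be > 0 and hypha_width_px >= 1")
        if self.noise_sd < 0 or self.jitter_sd_rad < 0:
            raise ValueError("noise_sd and jitter_sd_rad must be >= 0")
        if self.max_tips < self.n_tips0:
            raise ValueError("max_tips must be >= n_tips0")


def simulate_mycelium(params: MyceliumParams) -> tuple[np.ndarray, np.ndarray]:
    """Grow a branching filament network and rasterise it.

    Tips start evenly spaced on the left edge heading right (+x).  Each
    step every live tip turns by N(0, jitter_sd_rad), advances step_len_px,
    and with probability branch_prob spawns a daughter tip at
    ±branch_angle_rad relative to its own heading.  Tips leaving the canvas
    are terminated (bounded field of view, no wraparound), and no daughter
    is spawned once ``max_tips`` tips are alive — a carrying capacity that
    keeps the network density saturating, as it does in a real field of
    view, instead of growing exponentially without bound.

    Returns
    -------
    image : (H, W) uint8
        Rendered grayscale image: strokes at ``fg_level`` on ``bg_level``,
        then a linear illumination gradient of amplitude ``illum_amp``
        across x (clipped to 8-bit), then additive Gaussian noise of s.d.
        ``noise_sd`` (clipped again).
    skeleton : (H, W) bool
        Ground-truth mask of all stroked pixels (after widening to
        ``hypha_width_px``, before illumination/noise).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.height_px, params.width_px
    skel = np.zeros((H, W), dtype=bool)

    # tip state: [x, y, heading]; heading 0 points right, y grows downward
    tips: list[list[float]] = []
    for i in range(params.n_tips0):
        y0 = H * (i + 1) / (params.n_tips0 + 1)
        tips.append([0.0, y0, 0.0])

    for _ in range(params.n_steps):
        new_tips: list[list[float]] = []
        survivors: list[list[float]] = []
        for tip in tips:
            x, y, heading = tip
            heading = heading + rng.normal(0.0, params.jitter_sd_rad)
            nx = x + params.step_len_px * math.cos(heading)
            ny = y + params.step_len_px * math.sin(heading)
            _stroke(skel, x, y, nx, ny)
            if rng.uniform() < params.branch_prob:
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                if len(tips) + len(new_tips) < params.max_tips:
                    new_tips.append([nx, ny, heading + sign * params.branch_angle_rad])
            if 0.0 <= nx < W and 0.0 <= ny < H:
                survivors.append([nx, ny, heading])
        # daughters outside the canvas die immediately
        tips = survivors + [t for t in new_tips if 0.0 <= t[0] < W and 0.0 <= t[1] < H]
        if not tips:
            break

    if params.hypha_width_px > 1:
        # widened to the nearest odd stroke width (2*(w//2) + 1)
        skel = binary_dilation(skel, structure=_disk_footprint(params.hypha_width_px // 2))

    img = np.full((H, W), float(params.bg_level))
    if params.illum_amp != 0.0:
        ramp = params.illum_amp * (np.arange(W) / max(W - 1, 1) - 0.5)
        img = img + ramp[np.newaxis, :]
    img[skel] = float(params.fg_level)
    img = np.clip(img, 0.0, 255.0)
    if params.noise_sd > 0.0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 255.0)
    return np.floor(img + 0.5).astype(np.uint8), skel


def _stroke(mask: np.ndarray, x0: float, y0: float, x1: float, y1: float) -> None:
    """Rasterise segment (x0,y0)->(x1,y1) into mask, clipped to the canvas."""
    H, W = mask.shape
    rr, cc = _line_px(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
    keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    mask[rr[keep], cc[keep]] = True


# ---------------------------------------------------------------------------
# analytic fractal fixtures


@dataclass(frozen=True)
class FractalFixtureSpec:
    """A binary fixture with analytically known box-counting dimension."""

    kind: str  # line | filled_square | sierpinski_carpet | random_dust
    size_px: int
    level: int | None = None  # sierpinski_carpet only
    density: float | None = None  # random_dust only
    seed: int | None = None  # random_dust only

    def validate(self) -> None:
        kinds = {"line", "filled_square", "sierpinski_carpet", "random_dust"}
        if self.kind not in kinds:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.size_px < 1:
            raise ValueError("size_px must be positive")
        if self.kind == "sierpinski_carpet":
            if self.level is None or self.level < 1:
                raise ValueError("sierpinski_carpet requires level >= 1")
            if self.size_px != 3 ** self.level:
                raise ValueError("sierpinski_carpet requires size_px == 3**level")
        if self.kind == "random_dust":
            if self.density is None or not 0.0 < self.density <= 1.0:
                raise ValueError("random_dust requires density in (0, 1]")
            if self.seed is None:
                raise ValueError("random_dust requires a seed")


def render_fractal(spec: FractalFixtureSpec) -> np.ndarray:
    """Construct the exact pixel set of the requested fixture."""
    spec.validate()
    n = spec.size_px
    if spec.kind == "filled_square":
        return np.ones((n, n), dtype=bool)
    if spec.kind == "line":
        mask = np.zeros((n, n), dtype=bool)
        mask[n // 2, :] = True
        return mask
    if spec.kind == "sierpinski_carpet":
        idx = np.arange(n)
        keep = np.ones((n, n), dtype=bool)
        for k in range(spec.level):
            tri = (idx // 3 ** k) % 3 == 1
            keep &= ~(tri[:, None] & tri[None, :])
        return keep
    # random_dust
    rng = np.random.default_rng(spec.seed)
    n_on = int(math.floor(spec.density * n * n))
    flat = rng.choice(n * n, size=n_on, replace=False)
    mask = np.zeros(n * n, dtype=bool)
    mask[flat] = True
    return mask.reshape(n, n)


def theoretical_dimension(spec: FractalFixtureSpec) -> float | None:
    """Known dimension of a fixture, or None where it is not defined."""
    if spec.kind == "line":
        return 1.0
    if spec.kind == "filled_square":
        return 2.0
    if spec.kind == "sierpinski_carpet":
        return math.log(8) / math.log(3)
    return None


# ---------------------------------------------------------------------------
# pigmented drop scenes


@dataclass(frozen=True)
class DropSpec:
    centre_xy_px: tuple[float, float]
    radius_px: float
    red_fraction: float


@dataclass(frozen=True)
class DropSceneParams:
    """Circular media drops on a bright dish background.

    Inside each drop exactly ``floor(red_fraction * interior_area)`` pixels,
    chosen by the seeded RNG, are painted ``red_rgb``; the rest of the
    interior is ``medium_rgb``.  Default colours emulate a red fungal
    pigment in a pale medium photographed against a white dish.
    """

    seed: int
    width_px: int = 640
    height_px: int = 480
    drops: tuple[DropSpec, ...] = ()
    red_rgb: tuple[int, int, int] = (200, 30, 40)
    medium_rgb: tuple[int, int, int] = (235, 235, 200)
    bg_rgb: tuple[int, int, int] = (250, 250, 250)
    noise_sd: float = 4.0

    def validate(self) -> None:
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("canvas too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d in self.drops:
            cx, cy = d.centre_xy_px
            r = d.radius_px
            if r <= 0:
                raise ValueError("drop radius must be positive")
            if not 0.0 <= d.red_fraction <= 1.0:
                raise ValueError("red_fraction must lie in [0, 1]")
            if cx - r < 0 or cy - r < 0 or cx + r > self.width_px - 1 or cy + r > self.height_px - 1:
                raise ValueError("drop extends outside the canvas")
        for i, a in enumerate(self.drops):
            for b in self.drops[i + 1 :]:
                dist = math.hypot(
                    a.centre_xy_px[0] - b.centre_xy_px[0],
                    a.centre_xy_px[1] - b.centre_xy_px[1],
                )
                if dist <= a.radius_px + b.radius_px:
                    raise ValueError("ambiguous ground truth: drops overlap")


def render_drop_scene(params: DropSceneParams) -> tuple[np.ndarray, list[float]]:
    """Render the scene; return (RGB uint8 image, per-drop true red fraction).

    The returned fractions are the realised ground truth
    ``floor(red_fraction * |interior|) / |interior|``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.height_px, params.width_px
    img = np.empty((H, W, 3), dtype=float)
    img[...] = np.asarray(params.bg_rgb, dtype=float)

    truths: list[float] = []
    for d in params.drops:
        cx, cy = d.centre_xy_px
        rr, cc = _disk_px((cy, cx), d.radius_px + 0.5, shape=(H, W))
        n_int = rr.size
        if n_int == 0:
            raise ValueError("degenerate drop: empty interior")
        img[rr, cc] = np.asarray(params.medium_rgb, dtype=float)
        n_red = int(math.floor(d.red_fraction * n_int))
        pick = rng.choice(n_int, size=n_red, replace=False)
        img[rr[pick], cc[pick]] = np.asarray(params.red_rgb, dtype=float)
        truths.append(n_red / n_int)

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return np.floor(img + 0.5).astype(np.uint8), truths
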