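"""Synthetic grey-image generators with analytic ground-truth edge masks.

The evaluation protocol needs images whose true boundaries are known
exactly: a banded "rainbow" image (five full-width stripes on a uniform
background, i.e. six horizontal boundary lines), ideal steps, uniform
fields, checkerboards, and a smooth low-contrast phantom that emulates the
intensity statistics of a smooth clinical MR slice.  Every generator is a
pure function of its parameters (plus a seed where randomness is involved),
so fixtures are bit-reproducible.

Ground truth marks *both* pixels flanking each intensity discontinuity of
the generator geometry (an edge detector may legitimately respond on either
side), and never touches the 1-pixel border frame, matching the detectors'
border policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Fixture",
    "make_uniform",
    "make_step",
    "make_checkerboard",
    "make_rainbow",
    "make_smooth_phantom",
]

#: Default stripe levels; every stripe differs from its vertical neighbours
#: and from the background by at least 80 grey levels, which saturates the
#: detector's Higher set at each interface.
DEFAULT_BAND_LEVELS = (0, 80, 160, 55, 135)
DEFAULT_BACKGROUND = 240


@dataclass
class Fixture:
    """A synthetic image together with its analytic boundary mask."""

    image: np.ndarray
    truth: np.ndarray
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.truth.shape:
            raise ValueError("image and truth must share a shape")


def _discontinuity_mask(region: np.ndarray) -> np.ndarray:
    """Both-sided boundary mask of a piecewise-constant region image."""
    footprint = np.ones((3, 3))
    hi = ndimage.maximum_filter(region, footprint=footprint)
    lo = ndimage.minimum_filter(region, footprint=footprint)
    truth = hi != lo
    truth[0, :] = truth[-1, :] = False
    truth[:, 0] = truth[:, -1] = False
    return truth


def _finish(image: np.ndarray, truth: np.ndarray, name: str, **params) -> Fixture:
    return Fixture(image=image.astype(np.uint8), truth=truth, name=name, params=params)


def make_uniform(width: int = 64, height: int = 64, level: int = 128) -> Fixture:
    """Constant image; the truth mask is empty."""
    if not (0 <= level <= 255):
        raise ValueError("level must lie in [0, 255]")
    image = np.full((height, width), level, dtype=np.int64)
    return _finish(image, np.zeros(image.shape, dtype=bool), "uniform",
                   width=width, height=height, level=level)


def make_step(
    width: int = 32,
    height: int = 32,
    orientation: str = "vertical",
    lo: int = 0,
    hi: int = 255,
) -> Fixture:
    """Ideal intensity step; truth marks the two rows/columns at the jump."""
    if orientation not in ("vertical", "horizontal"):
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    if not (0 <= lo <= 255 and 0 <= hi <= 255):
        raise ValueError("levels must lie in [0, 255]")
    image = np.full((height, width), lo, dtype=np.int64)
    if orientation == "vertical":
        image[:, width // 2 :] = hi
    else:
        image[height // 2 :, :] = hi
    truth = _discontinuity_mask(image) if lo != hi else np.zeros(image.shape, dtype=bool)
    return _finish(image, truth, "step",
                   width=width, height=height, orientation=orientation, lo=lo, hi=hi)


def make_checkerboard(
    width: int = 64, height: int = 64, cell: int = 8, lo: int = 0, hi: int = 255
) -> Fixture:
    """Checkerboard of ``cell`` x ``cell`` squares; truth marks the grid lines."""
    if cell < 1:
        raise ValueError("cell size must be positive")
    rows = np.arange(height) // cell
    cols = np.arange(width) // cell
    parity = (rows[:, None] + cols[None, :]) % 2
    image = np.where(parity == 0, lo, hi).astype(np.int64)
    truth = _discontinuity_mask(image) if lo != hi else np.zeros(image.shape, dtype=bool)
    return _finish(image, truth, "checkerboard",
                   width=width, height=height, cell=cell, lo=lo, hi=hi)


def make_rainbow(
    width: int = 314,
    height: int = 192,
    bands: int = 5,
    band_height: int = 20,
    levels: Sequence[int] = DEFAULT_BAND_LEVELS,
    background: int = DEFAULT_BACKGROUND,
    min_contrast: int = 80,
) -> Fixture:
    """Banded image: full-width horizontal stripes centred on a background.

    With the default five stripes on a background the truth mask consists of
    exactly six straight horizontal boundary lines (two background
    interfaces plus four stripe-to-stripe interfaces); with
    ``bands * band_height == height`` the background disappears and only the
    internal interfaces remain.

    Stripe levels must be distinct and differ from their vertical neighbours
    and from the background by at least ``min_contrast`` grey levels so that
    every interface is unambiguous.
    """
    levels = tuple(int(v) for v in levels)
    if len(levels) != bands:
        raise ValueError(f"need {bands} stripe levels, got {len(levels)}")
    if bands * band_height > height:
        raise ValueError("stripes do not fit in the image height")
    if len(set(levels)) != len(levels):
        raise ValueError("stripe levels must be distinct")
    for v in levels + (background,):
        if not (0 <= v <= 255):
            raise ValueError("grey levels must lie in [0, 255]")
    full_height = bands * band_height == height
    for i, v in enumerate(levels):
        neighbours = []
        if i > 0:
            neighbours.append(levels[i - 1])
        if i + 1 < bands:
            neighbours.append(levels[i + 1])
        if not full_height and (i == 0 or i == bands - 1):
            neighbours.append(background)
        for nb in neighbours:
            if abs(v - nb) < min_contrast:
                raise ValueError(
                    f"stripe level {v} differs from neighbour {nb} by less "
                    f"than {min_contrast} grey levels"
                )

    image = np.full((height, width), background, dtype=np.int64)
    top = (height - bands * band_height) // 2
    for i, v in enumerate(levels):
        r0 = top + i * band_height
        image[r0 : r0 + band_height, :] = v
    truth = _discontinuity_mask(image)
    return _finish(image, truth, "rainbow",
                   width=width, height=height, bands=bands, band_height=band_height,
                   levels=levels, background=background)


def make_smooth_phantom(
    width: int = 270,
    height: int = 290,
    blobs: int = 3,
    amplitude: int = 35,
    smoothness: float = 2.0,
    background: int = 120,
    seed: int = 0,
) -> Fixture:
    """Low-contrast smooth phantom: soft elliptical blobs on a mid-grey field.

    The generator emulates the intensity regime of a smooth clinical image —
    weak contrasts (``|amplitude| <= 40``) and gently blurred boundaries —
    without reproducing any anatomy.  Truth marks both sides of the
    pre-blur ellipse boundaries.
    """
    if not (0 <= amplitude <= 40):
        raise ValueError("amplitude must lie in [0, 40] for a low-contrast phantom")
    if blobs < 0:
        raise ValueError("blob count must be non-negative")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    region = np.full((height, width), float(background))
    for i in range(blobs):
        if blobs == 1:
            cy, cx = height / 2.0, width / 2.0
        else:
            cy = rng.uniform(0.25 * height, 0.75 * height)
            cx = rng.uniform(0.25 * width, 0.75 * width)
        ay = rng.uniform(height / 10.0, height / 5.0)
        ax = rng.uniform(width / 10.0, width / 5.0)
        sign = 1.0 if i % 2 == 0 else -1.0
        amp = sign * amplitude * (0.6 + 0.4 * rng.random())
        mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        region[mask] += amp
    region = np.clip(region, 0, 255)
    truth = _discontinuity_mask(region)
    image = np.clip(np.rint(ndimage.gaussian_filter(region, smoothness)), 0, 255)
    return _finish(image.astype(np.int64), truth, "smooth_phantom",
                   width=width, height=height, blobs=blobs, amplitude=amplitude,
                   smoothness=smoothness, background=background, seed=seed)
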