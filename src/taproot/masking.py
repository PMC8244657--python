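"""Binary-mask extraction from RGB photographs of single roots.

A root is photographed on a contrasting background (black felt or white
vinyl). The image is converted to grayscale, smoothed with an
edge-preserving bilateral filter, thresholded, and reduced to the single
largest connected component with holes filled. Physical scale enters as
millimetres per pixel, conventionally derived from the pixel length of a
100 mm scale bar encoded in the filename.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_bilateral

from .errors import AmbiguousForegroundError, NoForegroundError

__all__ = [
    "MaskingConfig",
    "RootMask",
    "rgb_to_mask",
    "scale_from_bar",
    "read_mask_png",
    "write_mask_png",
]


@dataclass(frozen=True)
class MaskingConfig:
    """Parameters of the grayscale → bilateral filter → threshold chain.

    ``background_polarity`` is ``"dark"`` when the root is brighter than the
    background (black felt) and ``"light"`` for a white backdrop, in which
    case the thresholded image is inverted. ``threshold`` is either an
    integer gray level in 0–255 or ``"otsu"``.
    """

    background_polarity: str = "dark"
    threshold: int | str = "otsu"
    bilateral_spatial_sigma: float = 3.0
    bilateral_range_sigma: float = 0.1
    min_component_area_px: int = 64

    def __post_init__(self):
        if self.background_polarity not in ("dark", "light"):
            raise ValueError(f"unknown background_polarity {self.background_polarity!r}")
        if isinstance(self.threshold, str):
            if self.threshold != "otsu":
                raise ValueError(f"threshold must be an integer or 'otsu', got {self.threshold!r}")
        elif not 0 <= int(self.threshold) <= 255:
            raise ValueError(f"threshold {self.threshold} outside 0–255")
        if self.bilateral_spatial_sigma <= 0 or self.bilateral_range_sigma <= 0:
            raise ValueError("bilateral sigmas must be positive")


@dataclass
class RootMask:
    """Binary raster of a single root plus physical scale and identity.

    ``raster`` is a 2-D boolean array, True = root, oriented shoulder-up
    (row 0 nearest the crown). ``mm_per_px`` converts pixel lengths to
    millimetres.
    """

    raster: np.ndarray
    mm_per_px: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def area_px(self) -> int:
        return int(self.raster.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.mm_per_px**2

    def with_raster(self, raster: np.ndarray) -> "RootMask":
        return replace(self, raster=np.asarray(raster, dtype=bool))


def scale_from_bar(bar_length_px: float) -> float:
    """Millimetres per pixel from the pixel length of a 100 mm scale bar."""
    if bar_length_px <= 0:
        raise ValueError(f"bar length must be positive, got {bar_length_px}")
    return 100.0 / bar_length_px


def _largest_component(binary: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(binary)
    if n == 0:
        raise NoForegroundError("no foreground component found")
    areas = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    order = np.argsort(areas)[::-1]
    if areas[order[0]] < min_area:
        raise NoForegroundError(
            f"largest component ({int(areas[order[0]])} px) below "
            f"min_component_area_px={min_area}"
        )
    if n > 1 and areas[order[1]] >= min_area:
        a0, a1 = areas[order[0]], areas[order[1]]
        if a1 >= 0.9 * a0:
            raise AmbiguousForegroundError(
                f"two components of similar area ({int(a0)} vs {int(a1)} px); "
                "cannot decide which is the root"
            )
    return labels == (order[0] + 1)


def rgb_to_mask(
    image: np.ndarray,
    config: MaskingConfig = MaskingConfig(),
    mm_per_px: float = 1.0,
    metadata: dict | None = None,
) -> RootMask:
    """Segment a root photograph into a clean single-component binary mask.

    Pipeline: grayscale → bilateral filter → binary threshold (inverted for
    a light background) → largest connected component → hole filling.

    Raises :class:`NoForegroundError` when nothing survives and
    :class:`AmbiguousForegroundError` when the two largest components are
    within 10% of each other in area.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = rgb2gray(image[..., :3])
    else:
        gray = image.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    gray = denoise_bilateral(
        gray,
        sigma_spatial=config.bilateral_spatial_sigma,
        sigma_color=config.bilateral_range_sigma,
    )
    if config.threshold == "otsu":
        thr = threshold_otsu(gray)
    else:
        thr = float(config.threshold) / 255.0
    binary = gray > thr
    if config.background_polarity == "light":
        binary = ~binary
    binary = _largest_component(binary, config.min_component_area_px)
    binary = ndimage.binary_fill_holes(binary)
    return RootMask(binary, mm_per_px=mm_per_px, metadata=dict(metadata or {}))


def read_mask_png(path: str | Path, mm_per_px: float = 1.0, metadata: dict | None = None) -> RootMask:
    """Read an 8-bit PNG mask (white = root)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return RootMask(arr > 127, mm_per_px=mm_per_px, metadata=dict(metadata or {}))


def write_mask_png(mask: RootMask, path: str | Path) -> None:
    """Write a mask as an 8-bit 0/255 PNG."""
    Image.fromarray(np.where(mask.raster, 255, 0).astype(np.uint8)).save(path)
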