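"""Gray-level normalization and ring/sector ROI handling.

Texture features are never computed on raw scanner intensities: the masked
pixels are first re-expressed on a fixed ``1..Ng`` gray-level scale by
clipping to the ROI's mean +/- 3 SD window and linearly rescaling.  This
makes every downstream feature invariant to positive affine changes of
image brightness/contrast, which vary freely between acquisitions.

Conventions (used consistently across the package):

* rasters are indexed ``(row, col)``, 0-based;
* polar angles are measured counter-clockwise from the +col axis, with the
  row axis pointing down (so "up" on screen is +90 deg);
* masks are boolean rasters aligned pixel-for-pixel with their image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "RoiMask",
    "QuantizedRoi",
    "MaskTooSmallError",
    "normalize_mu3sigma",
    "carve_sector",
    "annulus_mask",
    "read_gray",
    "read_mask",
    "write_gray",
    "write_mask",
]

MIN_MASK_AREA = 16

REGION_LABELS = ("whole_wall", "septal", "lateral")


class MaskTooSmallError(ValueError):
    """Raised when an ROI has too few pixels to support quantization."""


@dataclass(frozen=True)
class GrayImage:
    """A 2D non-negative integer intensity raster (arbitrary units)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("image must be 2D")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError("image must be at least 8x8")
        if np.any(px < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiMask:
    """A boolean ROI raster with a region label (whole_wall/septal/lateral)."""

    mask: np.ndarray
    region_label: str = "whole_wall"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region_label!r}")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QuantizedRoi:
    """Masked pixels mapped onto the ``1..n_levels`` gray scale.

    ``levels_raster`` is a full-size int raster (0 outside the mask) so that
    spatial features (gradient, co-occurrence, runs, AR, wavelet) retain the
    pixel geometry; ``levels`` gives the flat masked values.
    ``mu``/``sigma`` are the pre-normalization mean and SD of the masked raw
    intensities; ``degenerate`` marks a zero-variance ROI whose pixels were
    all assigned the mid-scale level.
    """

    levels_raster: np.ndarray
    mask: np.ndarray
    n_levels: int
    mu: float
    sigma: float
    degenerate: bool = False
    region_label: str = "whole_wall"

    def __post_init__(self) -> None:
        inside = self.levels_raster[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("levels out of range")

    @property
    def levels(self) -> np.ndarray:
        return self.levels_raster[self.mask]

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def normalize_mu3sigma(
    image: GrayImage | np.ndarray,
    roi: RoiMask | np.ndarray,
    n_levels: int = 64,
    region_label: str | None = None,
) -> QuantizedRoi:
    """Quantize the masked pixels to ``1..n_levels`` over the mu +/- 3 sigma window.

    A raw intensity ``v`` maps to::

        1 + floor((clip(v, mu-3s, mu+3s) - (mu-3s)) / (6s) * (n_levels-1) + 0.5)

    with ``mu``, ``s`` the mean and SD of the masked raw intensities
    (half-up rounding; values outside the window saturate at 1 / n_levels).
    A zero-variance ROI maps every pixel to ``round((n_levels+1)/2)`` and
    sets the ``degenerate`` flag.
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if isinstance(roi, RoiMask):
        mask = roi.mask
        if region_label is None:
            region_label = roi.region_label
    else:
        mask = np.asarray(roi, dtype=bool)
        if region_label is None:
            region_label = "whole_wall"
    if mask.shape != px.shape:
        raise ValueError("mask shape does not match image")
    if n_levels < 4:
        raise ValueError("n_levels must be >= 4")
    if mask.sum() < MIN_MASK_AREA:
        raise MaskTooSmallError("mask too small")

    vals = px[mask].astype(np.float64)
    mu = float(vals.mean())
    sigma = float(vals.std())  # population SD over the ROI

    out = np.zeros(px.shape, dtype=np.int32)
    if sigma == 0.0:
        mid = int(np.floor((n_levels + 1) / 2 + 0.5))
        out[mask] = mid
        return QuantizedRoi(out, mask, n_levels, mu, sigma, True, region_label)

    lo = mu - 3.0 * sigma
    z = (np.clip(vals, lo, mu + 3.0 * sigma) - lo) / (6.0 * sigma)
    lev = 1 + np.floor(z * (n_levels - 1) + 0.5).astype(np.int64)
    out[mask] = np.clip(lev, 1, n_levels)
    return QuantizedRoi(out, mask, n_levels, mu, sigma, False, region_label)


def pixel_angles(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Polar angle (degrees in [0, 360)) of every pixel about ``center``.

    Counter-clockwise from the +col axis; the row axis points down, so the
    sign of the row offset is flipped.
    """
    rows, cols = np.indices(shape)
    ang = np.degrees(np.arctan2(-(rows - center[0]), cols - center[1]))
    return np.mod(ang, 360.0)


def carve_sector(
    ring: RoiMask,
    center: tuple[float, float],
    center_angle_deg: float,
    span_deg: float = 120.0,
    region_label: str | None = None,
) -> RoiMask:
    """Keep the ring pixels whose polar angle lies within +/- span/2 of center_angle.

    Emulates placing a septal (center angle 180 deg) or lateral (0 deg)
    sector ROI on the myocardial ring.
    """
    if not (0.0 < span_deg <= 360.0):
        raise ValueError("span_deg must be in (0, 360]")
    if ring.area == 0:
        raise ValueError("ring is empty")
    if span_deg == 360.0:
        return RoiMask(ring.mask.copy(), region_label or ring.region_label)
    ang = pixel_angles(ring.mask.shape, center)
    delta = np.abs((ang - center_angle_deg + 180.0) % 360.0 - 180.0)
    sector = ring.mask & (delta <= span_deg / 2.0)
    if not sector.any():
        raise ValueError("sector misses ring")
    return RoiMask(sector, region_label or ring.region_label)


def annulus_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_inner: float,
    r_outer: float,
    region_label: str = "whole_wall",
) -> RoiMask:
    """Boolean ring ``r_inner <= r < r_outer`` about ``center`` (pixel centers)."""
    if not (0 < r_inner < r_outer):
        raise ValueError("need 0 < r_inner < r_outer")
    rows, cols = np.indices(shape)
    r = np.hypot(rows - center[0], cols - center[1])
    return RoiMask((r >= r_inner) & (r < r_outer), region_label)


# ---------------------------------------------------------------------------
# Raster I/O (PNG / TIFF)

def read_gray(path) -> GrayImage:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any accidental RGB to one channel
        arr = arr[..., 0]
    return GrayImage(arr.astype(np.int64))


def read_mask(path, region_label: str = "whole_wall") -> RoiMask:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return RoiMask(arr > 0, region_label)


def write_gray(path, image: GrayImage) -> None:
    iio.imwrite(path, image.pixels.astype(np.uint16))


def write_mask(path, roi: RoiMask) -> None:
    iio.imwrite(path, (roi.mask.astype(np.uint8) * 255))
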