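"""Pixel-based density, intensity, brightness and texture descriptors.

Measurements operate on a grayscale image plus a nucleus region.  The
working intensity is *optical*: on transmitted-light H&E images dense
chromatin is dark, so raw gray values are inverted against the white
level (255 for 8-bit, 65535 for 16-bit) before summation, making denser
chromatin yield higher sum/mean density.  Inversion can be disabled for
fluorescence-like images where bright already means dense.

Definitions
-----------
sum_intensity   total working intensity over the region
sum_density     sum of (working intensity x pixel area), i.e. integrated
                optical density in intensity*um^2
mean_density    sum_density normalized by region area (intensity per um^2
                times um^2 — numerically the mean working intensity for a
                uniform pixel grid)
brightness      mean working intensity
roughness       contour perimeter / convex-hull perimeter (>= 1; a texture
                surrogate for boundary irregularity)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .geometry import Contour, polygon_perimeter, validate_contour

__all__ = [
    "PixelRegion",
    "DensityDescriptors",
    "EmptyRegionError",
    "rasterize",
    "working_intensity",
    "sum_intensity",
    "sum_density",
    "brightness",
    "roughness",
    "measure_density",
]

#: Rec. 601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class EmptyRegionError(ValueError):
    """A contour rasterized to zero pixels inside the image."""


@dataclass(frozen=True)
class PixelRegion:
    """Integer pixel membership of one nucleus (row, col; origin top-left)."""

    nucleus_id: str
    rows: np.ndarray
    cols: np.ndarray
    pixel_area: float = 1.0  # um^2 per pixel

    @property
    def pixel_count(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class DensityDescriptors:
    sum_intensity: float
    sum_density: float
    mean_density: float
    brightness: float
    roughness: float
    pixel_count: int


def rasterize(
    c: Contour, image_shape: tuple[int, int], microns_per_pixel: float = 1.0
) -> PixelRegion:
    """Pixels whose centers lie inside the polygon (boundary counts inside).

    The pixel at (row, col) has its center at
    ``((col + 0.5) * mpp, (row + 0.5) * mpp)`` in the contour's micron frame.
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    mpp = microns_per_pixel
    poly = shapely.Polygon(c.vertices)
    h, w = image_shape[:2]
    x0, y0, x1, y1 = poly.bounds
    c0 = max(int(np.floor(x0 / mpp - 0.5)), 0)
    c1 = min(int(np.ceil(x1 / mpp)) + 1, w)
    r0 = max(int(np.floor(y0 / mpp - 0.5)), 0)
    r1 = min(int(np.ceil(y1 / mpp)) + 1, h)
    if c1 <= c0 or r1 <= r0:
        raise EmptyRegionError(f"nucleus {c.nucleus_id!r}: contour outside image")
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    centers = shapely.points(
        (cc.ravel() + 0.5) * mpp, (rr.ravel() + 0.5) * mpp
    )
    inside = shapely.covers(poly, centers)  # covers: boundary ties are inside
    if not inside.any():
        raise EmptyRegionError(f"nucleus {c.nucleus_id!r}: empty pixel region")
    return PixelRegion(
        nucleus_id=c.nucleus_id,
        rows=rr.ravel()[inside],
        cols=cc.ravel()[inside],
        pixel_area=mpp * mpp,
    )


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB(A) to grayscale via Rec. 601 luma; grayscale passes through."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        return image[..., :3].astype(float) @ _LUMA
    raise ValueError(f"unsupported image shape {image.shape}")


def working_intensity(image: np.ndarray, invert: bool = True) -> np.ndarray:
    """Grayscale image mapped to optical working intensity.

    With ``invert`` (the default for brightfield H&E), intensity is
    ``white_level - gray`` with the white level inferred from dtype
    (255 for 8-bit, 65535 for 16-bit, 1.0 for floats in [0, 1]).
    """
    gray = to_grayscale(image).astype(float)
    if not invert:
        return gray
    if image.dtype == np.uint8:
        white = 255.0
    elif image.dtype == np.uint16:
        white = 65535.0
    else:
        white = float(max(gray.max(), 1.0))
    return white - gray


def _region_values(region: PixelRegion, intensity: np.ndarray) -> np.ndarray:
    h, w = intensity.shape
    if region.pixel_count == 0:
        raise EmptyRegionError("empty region")
    if region.rows.max() >= h or region.cols.max() >= w:
        raise ValueError("region exceeds image bounds")
    return intensity[region.rows, region.cols]


def sum_intensity(region: PixelRegion, intensity: np.ndarray) -> float:
    """Total working intensity within the region."""
    return float(_region_values(region, intensity).sum())


def sum_density(region: PixelRegion, intensity: np.ndarray) -> float:
    """Integrated optical density: sum of intensity x pixel area."""
    return sum_intensity(region, intensity) * region.pixel_area


def brightness(region: PixelRegion, intensity: np.ndarray) -> float:
    """Mean working intensity within the region."""
    return sum_intensity(region, intensity) / region.pixel_count


def roughness(c: Contour) -> float:
    """Perimeter over convex-hull perimeter; 1 for convex contours."""
    hull = shapely.convex_hull(shapely.Polygon(c.vertices))
    hull_c = validate_contour(np.asarray(hull.exterior.coords)[:-1], c.nucleus_id)
    return polygon_perimeter(c) / polygon_perimeter(hull_c)


def measure_density(
    c: Contour,
    image: np.ndarray,
    microns_per_pixel: float = 1.0,
    invert: bool = True,
) -> DensityDescriptors:
    """All density-family descriptors for one nucleus on one image."""
    intensity = working_intensity(image, invert=invert)
    region = rasterize(c, intensity.shape, microns_per_pixel)
    si = sum_intensity(region, intensity)
    sd = si * region.pixel_area
    return DensityDescriptors(
        sum_intensity=si,
        sum_density=sd,
        mean_density=sd / (region.pixel_count * region.pixel_area),
        brightness=si / region.pixel_count,
        roughness=roughness(c),
        pixel_count=region.pixel_count,
    )
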