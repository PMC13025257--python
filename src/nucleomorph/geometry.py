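"""Contour-based nuclear size and shape descriptors.

A traced nucleus boundary is treated as a simple planar polygon with
vertices in micrometers.  From it we derive the classical morphometric
family: area, circumference (perimeter), circle-equivalent diameter,
formfactor (4*pi*A/P**2, the circularity index), and the Feret diameters
(extents between parallel tangents): MinFeret, MaxFeret, and MaxFeret90 —
the Feret diameter measured perpendicular to the MaxFeret chord.  The
difference MaxFeret - MaxFeret90 (Feret asymmetry) indexes contour
irregularity.

Feret quantities are computed on the convex hull; for these
parallel-tangent definitions the hull and the raw contour coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely

__all__ = [
    "Contour",
    "ShapeDescriptors",
    "InvalidContourError",
    "validate_contour",
    "polygon_area",
    "polygon_perimeter",
    "equivalent_diameter",
    "formfactor",
    "feret_extremes",
    "feret_width",
    "max_feret90",
    "measure_shape",
]

#: contours with area below this (um^2) are manual-tracing artifacts
MIN_AREA_UM2 = 1e-6


class InvalidContourError(ValueError):
    """Raised for degenerate or self-intersecting nucleus contours."""


@dataclass(frozen=True)
class Contour:
    """An ordered, closed, counter-clockwise simple polygon in micrometers."""

    nucleus_id: str
    vertices: np.ndarray  # (n, 2) float64, implicitly closed

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class ShapeDescriptors:
    """Per-nucleus size and shape measurements (micrometer units)."""

    area: float
    circumference: float
    equivalent_diameter: float
    formfactor: float
    min_feret: float
    max_feret: float
    max_feret90: float
    feret_asymmetry: float


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def validate_contour(raw_vertices: Sequence, nucleus_id: str = "") -> Contour:
    """Normalize a raw vertex list into a validated :class:`Contour`.

    Removes duplicate consecutive vertices (including a repeated closing
    vertex), enforces counter-clockwise orientation, and rejects polygons
    with fewer than 3 distinct vertices, self-intersections, or negligible
    area (< ``MIN_AREA_UM2``).
    """
    v = np.asarray(raw_vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise InvalidContourError("vertices must be an (n, 2) coordinate list")
    if not np.all(np.isfinite(v)):
        raise InvalidContourError("non-finite coordinates")
    # drop consecutive duplicates, treating the list as cyclic
    keep = np.any(v != np.roll(v, -1, axis=0), axis=1)
    v = v[keep]
    if len(v) < 3:
        raise InvalidContourError("fewer than 3 distinct vertices")
    poly = shapely.Polygon(v)
    if not poly.is_valid or poly.area <= 0.0:
        raise InvalidContourError("self-intersecting or degenerate contour")
    if poly.area < MIN_AREA_UM2:
        raise InvalidContourError(
            f"contour area {poly.area:g} um^2 below measurable minimum"
        )
    if _signed_area(v) < 0:
        v = v[::-1]
    return Contour(nucleus_id=nucleus_id, vertices=v)


def polygon_area(c: Contour) -> float:
    """Shoelace area in um^2 (strictly positive for a valid contour)."""
    return _signed_area(c.vertices)


def polygon_perimeter(c: Contour) -> float:
    """Circumference in um: sum of edge lengths including the closing edge."""
    d = np.roll(c.vertices, -1, axis=0) - c.vertices
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given area: 2*sqrt(area/pi)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area / math.pi)


def formfactor(area: float, circumference: float) -> float:
    """Circularity index 4*pi*area/circumference**2, in (0, 1]."""
    if area <= 0 or circumference <= 0:
        raise ValueError("area and circumference must be positive")
    return 4.0 * math.pi * area / circumference**2


def _hull_vertices(c: Contour) -> np.ndarray:
    hull = shapely.convex_hull(shapely.MultiPoint(c.vertices))
    if not isinstance(hull, shapely.Polygon):
        raise InvalidContourError("degenerate (collinear) convex hull")
    hv = np.asarray(hull.exterior.coords)[:-1]
    if len(hv) < 3:
        raise InvalidContourError("degenerate (collinear) convex hull")
    return hv


def feret_extremes(c: Contour) -> tuple[float, float, float]:
    """(MinFeret, MaxFeret, direction of the MaxFeret chord in radians).

    MaxFeret is the maximum pairwise distance between hull vertices
    (the rotating-calipers diameter); MinFeret is the minimum width over
    hull-edge-normal directions, where the global minimum width is always
    attained.  Ties in the maximum chord resolve to the smallest vertex
    index pair for determinism.
    """
    hv = _hull_vertices(c)
    n = len(hv)
    # max Feret: all pairwise hull-vertex distances
    diff = hv[:, None, :] - hv[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if i > j:
        i, j = j, i
    max_f = math.sqrt(d2[i, j])
    chord = hv[j] - hv[i]
    direction = math.atan2(chord[1], chord[0])
    # min Feret: for each hull edge, max distance of vertices from its line
    e = np.roll(hv, -1, axis=0) - hv
    lengths = np.hypot(e[:, 0], e[:, 1])
    ok = lengths > 0
    normals = np.stack([-e[ok, 1], e[ok, 0]], axis=1) / lengths[ok, None]
    # widths: for each edge direction, extent of projections onto its normal
    proj = normals @ hv.T  # (n_edges, n_vertices)
    widths = proj.max(axis=1) - proj.min(axis=1)
    min_f = float(widths.min())
    return min_f, max_f, direction


def feret_width(c: Contour, direction: float) -> float:
    """Extent of the vertex projections onto the unit vector of *direction*."""
    u = np.array([math.cos(direction), math.sin(direction)])
    p = c.vertices @ u
    return float(p.max() - p.min())


def max_feret90(c: Contour) -> float:
    """Feret diameter perpendicular to the MaxFeret chord."""
    _, _, direction = feret_extremes(c)
    return feret_width(c, direction + math.pi / 2.0)


def measure_shape(c: Contour) -> ShapeDescriptors:
    """All size and shape descriptors of one nucleus contour."""
    area = polygon_area(c)
    perim = polygon_perimeter(c)
    min_f, max_f, direction = feret_extremes(c)
    mf90 = feret_width(c, direction + math.pi / 2.0)
    return ShapeDescriptors(
        area=area,
        circumference=perim,
        equivalent_diameter=equivalent_diameter(area),
        formfactor=formfactor(area, perim),
        min_feret=min_f,
        max_feret=max_f,
        max_feret90=mf90,
        feret_asymmetry=max_f - mf90,
    )
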