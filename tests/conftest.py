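"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (fan triangulation, dense
angular sweeps, full enumeration) and independent of the library code
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from nucleomorph.geometry import Contour, validate_contour


def random_star_polygon(
    rng: np.random.Generator, n_vertices: int = 12, irregularity: float = 0.3
) -> Contour:
    """A random simple polygon: star-convex radial perturbation of a circle."""
    from nucleomorph.geometry import InvalidContourError

    for _ in range(100):
        theta = np.sort(rng.uniform(0.0, 2.0 * math.pi, n_vertices))
        # well-separated angles spanning the circle keep the polygon simple
        if np.any(np.diff(theta) < 1e-3) or theta[-1] - theta[0] < math.pi:
            continue
        r = rng.uniform(
            1.0 - irregularity, 1.0 + irregularity, n_vertices
        ) * rng.uniform(1.0, 10.0)
        verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        try:
            return validate_contour(verts, "star")
        except InvalidContourError:
            continue
    raise RuntimeError("could not draw a valid star polygon")


def fan_triangulation_area(vertices: np.ndarray) -> float:
    """Area as a fan of triangles from vertex 0 (signed cross products)."""
    total = 0.0
    v0 = vertices[0]
    for a, b in zip(vertices[1:-1], vertices[2:]):
        total += 0.5 * ((a[0] - v0[0]) * (b[1] - v0[1]) - (b[0] - v0[0]) * (a[1] - v0[1]))
    return abs(total)


def edgewise_perimeter(vertices: np.ndarray) -> float:
    total = 0.0
    n = len(vertices)
    for i in range(n):
        dx, dy = vertices[(i + 1) % n] - vertices[i]
        total += math.hypot(dx, dy)
    return total


def sweep_feret(vertices: np.ndarray, n_directions: int = 3600) -> tuple[float, float]:
    """(min, max) Feret by brute-force projection over a dense angle grid."""
    angles = np.linspace(0.0, math.pi, n_directions, endpoint=False)
    u = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = u @ vertices.T  # (n_directions, n_vertices)
    widths = proj.max(axis=1) - proj.min(axis=1)
    return float(widths.min()), float(widths.max())


def enumerate_mann_whitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every group labeling."""
    x, y = list(x), list(y)
    pooled = x + y
    n, n1 = len(pooled), len(x)
    # midranks: tied values share the average of their positional ranks
    ranks = [0.0] * n
    for i in range(n):
        less = sum(1 for v in pooled if v < pooled[i])
        equal = sum(1 for v in pooled if v == pooled[i])
        ranks[i] = less + (equal + 1) / 2.0

    def u_stat(idx: tuple[int, ...]) -> float:
        rank_sum = sum(ranks[i] for i in idx)
        return rank_sum - n1 * (n1 + 1) / 2.0

    observed = u_stat(tuple(range(n1)))
    mean_u = n1 * (n - n1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_stat(idx) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def unit_square() -> Contour:
    return validate_contour([(0, 0), (1, 0), (1, 1), (0, 1)], "sq")


@pytest.fixture
def rect_4x1() -> Contour:
    return validate_contour([(0, 0), (4, 0), (4, 1), (0, 1)], "rect")
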