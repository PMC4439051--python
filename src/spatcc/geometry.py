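"""Planar point-pattern primitives: study windows, intensity, and Ripley's K function.

All coordinates are planar meters (the analyses this package supports assume a
projected CRS such as a UTM zone). The central estimator is Ripley's K
function

    K(s) = E[number of further events within distance s of a typical event] / lambda,

estimated on a finite study window either without edge correction,

    K_hat(s) = (1 / lambda_hat) (1/n) sum_i #{j != i : d_ij <= s},

or with Ripley's isotropic edge correction, where each ordered pair (i, j)
with d_ij <= s contributes a weight w_ij equal to the reciprocal of the
proportion of the circle centered at i with radius d_ij whose circumference
lies inside the window. Under complete spatial randomness K(s) = pi s^2,
which is the benchmark the tests lean on.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist
from shapely import wkt as _shapely_wkt
from shapely.geometry import Point, Polygon, shape

__all__ = [
    "StudyWindow",
    "PointPattern",
    "KEstimate",
    "intensity",
    "pairwise_distances",
    "k_function",
    "default_s_grid",
    "DEFAULT_S_MAX",
]

#: Maximum distance (meters) of the default K-function grid.
DEFAULT_S_MAX = 8000.0
#: Number of grid points in the default K-function grid.
DEFAULT_S_POINTS = 64


class EmptyPatternError(ValueError):
    """Raised when an operation needs points that the pattern does not have."""


@dataclasses.dataclass(frozen=True)
class StudyWindow:
    """A simple (non-self-intersecting, hole-free) polygonal study region.

    Parameters
    ----------
    boundary
        Shapely polygon in planar meters. Must be simple, with positive area
        and no interior rings.
    crs_tag
        Free-text metadata (e.g. ``"EPSG:25830"``). Never interpreted.
    """

    boundary: Polygon
    crs_tag: str = ""

    def __post_init__(self) -> None:
        poly = self.boundary
        if not isinstance(poly, Polygon):
            raise TypeError("boundary must be a shapely Polygon")
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("study window polygon must be simple and valid")
        if len(poly.interiors) > 0:
            raise ValueError("study window polygon must not have holes")
        if poly.area <= 0:
            raise ValueError("study window must have positive area")

    @property
    def area(self) -> float:
        """Window area in square meters."""
        return float(self.boundary.area)

    @classmethod
    def rectangle(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, crs_tag: str = ""
    ) -> "StudyWindow":
        """Axis-aligned rectangular window."""
        return cls(
            Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)]),
            crs_tag=crs_tag,
        )

    @classmethod
    def from_wkt(cls, text: str, crs_tag: str = "") -> "StudyWindow":
        """Window from a WKT ``POLYGON`` string."""
        return cls(_shapely_wkt.loads(text), crs_tag=crs_tag)

    @classmethod
    def from_geojson(cls, obj, crs_tag: str = "") -> "StudyWindow":
        """Window from a GeoJSON Polygon (mapping, JSON string, or file path)."""
        if isinstance(obj, (str, Path)):
            p = Path(obj)
            if p.exists():
                obj = json.loads(p.read_text())
            else:
                obj = json.loads(str(obj))
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        elif obj.get("type") == "FeatureCollection":
            feats = obj["features"]
            if len(feats) != 1:
                raise ValueError("expected a single polygon feature")
            obj = feats[0]["geometry"]
        return cls(shape(obj), crs_tag=crs_tag)

    def to_geojson(self) -> dict:
        from shapely.geometry import mapping

        return dict(mapping(self.boundary))

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask: point inside or on the boundary (boundary counts inside)."""
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[None, :]
        import shapely

        return shapely.covers(self.boundary, shapely.points(coords))

    def exterior_ring(self) -> tuple[np.ndarray, np.ndarray]:
        """Closed exterior ring as (x, y) arrays (first vertex repeated last)."""
        xs, ys = self.boundary.exterior.coords.xy
        return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


@dataclasses.dataclass(frozen=True)
class PointPattern:
    """A finite planar point set observed in a study window."""

    coords: np.ndarray
    window: StudyWindow

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        if coords.shape[0] and not np.all(self.window.contains(coords)):
            raise ValueError("all points must lie inside or on the window boundary")

    @property
    def n(self) -> int:
        return int(self.coords.shape[0])


@dataclasses.dataclass(frozen=True)
class KEstimate:
    """Estimated K function on a distance grid.

    ``k_values[i]`` estimates K at ``s_grid[i]`` (units m^2); ``lambda_hat``
    is the intensity estimate n/|A| used in the normalization.
    """

    s_grid: np.ndarray
    k_values: np.ndarray
    correction: str
    lambda_hat: float


def default_s_grid(
    s_max: float = DEFAULT_S_MAX, n_points: int = DEFAULT_S_POINTS
) -> np.ndarray:
    """Equally spaced grid ``s_max/n, 2 s_max/n, ..., s_max``."""
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    return np.linspace(s_max / n_points, s_max, n_points)


def intensity(pattern: PointPattern) -> float:
    """Overall intensity lambda_hat = n / |A| in points per square meter."""
    if pattern.n < 1:
        raise EmptyPatternError("intensity is undefined for an empty pattern")
    return pattern.n / pattern.window.area


def pairwise_distances(pattern: PointPattern) -> np.ndarray:
    """Symmetric Euclidean distance matrix in meters; requires n >= 2."""
    if pattern.n < 2:
        raise EmptyPatternError("need at least 2 points for pairwise distances")
    return cdist(pattern.coords, pattern.coords)


# ---------------------------------------------------------------------------
# numba kernels for the isotropic edge correction
# ---------------------------------------------------------------------------


@njit(cache=True)
def _point_in_ring(x: float, y: float, rx: np.ndarray, ry: np.ndarray) -> bool:
    # even-odd ray casting against the closed ring (rx[0] == rx[-1])
    inside = False
    for k in range(rx.shape[0] - 1):
        y1 = ry[k]
        y2 = ry[k + 1]
        if (y1 > y) != (y2 > y):
            xcross = rx[k] + (y - y1) * (rx[k + 1] - rx[k]) / (y2 - y1)
            if xcross > x:
                inside = not inside
    return inside


@njit(cache=True)
def _boundary_fraction(
    cx: float, cy: float, r: float, rx: np.ndarray, ry: np.ndarray
) -> float:
    """Fraction of the circle |p - c| = r whose circumference lies inside the ring.

    Exact up to point-in-polygon tests: intersection angles of the circle with
    every polygon edge split the circle into arcs, and each arc is classified
    by its midpoint.
    """
    nseg = rx.shape[0] - 1
    angs = np.empty(2 * nseg, dtype=np.float64)
    na = 0
    for k in range(nseg):
        dx = rx[k + 1] - rx[k]
        dy = ry[k + 1] - ry[k]
        fx = rx[k] - cx
        fy = ry[k] - cy
        a = dx * dx + dy * dy
        if a == 0.0:
            continue
        b = 2.0 * (fx * dx + fy * dy)
        c = fx * fx + fy * fy - r * r
        disc = b * b - 4.0 * a * c
        if disc <= 0.0:
            continue  # no crossing (tangency leaves the arc classification unchanged)
        sq = math.sqrt(disc)
        for sgn in (-1.0, 1.0):
            t = (-b + sgn * sq) / (2.0 * a)
            if 0.0 <= t <= 1.0:
                px = rx[k] + t * dx
                py = ry[k] + t * dy
                angs[na] = math.atan2(py - cy, px - cx)
                na += 1
    if na == 0:
        # circle does not cross the boundary: fully inside or fully outside
        if _point_in_ring(cx + r, cy, rx, ry):
            return 1.0
        return 0.0
    srt = np.sort(angs[:na])
    total = 0.0
    for k in range(na):
        a0 = srt[k]
        a1 = srt[k + 1] if k + 1 < na else srt[0] + 2.0 * math.pi
        mid = 0.5 * (a0 + a1)
        if _point_in_ring(cx + r * math.cos(mid), cy + r * math.sin(mid), rx, ry):
            total += a1 - a0
    return total / (2.0 * math.pi)


@njit(cache=True)
def _pair_weights_bins(
    coords: np.ndarray,
    s_grid: np.ndarray,
    rx: np.ndarray,
    ry: np.ndarray,
    isotropic: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ordered-pair edge weights and distance-grid bin indices.

    W[i, j] is the isotropic weight of ordered pair (i, j) if d_ij <= s_max,
    else 0. B[i, j] is the first grid index b with d_ij <= s_grid[b] (len(s_grid)
    when the pair is beyond s_max); cumulative sums over bins give K hat.
    """
    n = coords.shape[0]
    nb = s_grid.shape[0]
    smax = s_grid[nb - 1]
    W = np.zeros((n, n), dtype=np.float64)
    B = np.full((n, n), nb, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            d = math.sqrt(dx * dx + dy * dy)
            if d > smax:
                continue
            b = np.searchsorted(s_grid, d)
            wij = 1.0
            wji = 1.0
            if isotropic and d > 0.0:
                f = _boundary_fraction(coords[i, 0], coords[i, 1], d, rx, ry)
                wij = 1.0 / f if f > 1e-12 else 0.0
                f = _boundary_fraction(coords[j, 0], coords[j, 1], d, rx, ry)
                wji = 1.0 / f if f > 1e-12 else 0.0
            W[i, j] = wij
            W[j, i] = wji
            B[i, j] = b
            B[j, i] = b
    return W, B


def isotropic_weight(window: StudyWindow, center: Sequence[float], radius: float) -> float:
    """Ripley's isotropic edge-correction weight for one (center, radius) pair.

    The reciprocal of the proportion of the circle's circumference inside the
    window; 1.0 whenever the full circle lies inside.
    """
    if radius <= 0:
        return 1.0
    rx, ry = window.exterior_ring()
    f = _boundary_fraction(float(center[0]), float(center[1]), float(radius), rx, ry)
    if f <= 1e-12:
        # degenerate geometry: no part of the circumference is observable
        return 0.0
    return 1.0 / f


def pair_weights_and_bins(
    coords: np.ndarray,
    window: StudyWindow,
    s_grid: np.ndarray,
    correction: str = "isotropic",
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute (W, B) pair matrices reusable across label permutations."""
    if correction not in ("none", "isotropic"):
        raise ValueError("correction must be 'none' or 'isotropic'")
    coords = np.ascontiguousarray(np.asarray(coords, dtype=float))
    s_grid = _validate_s_grid(s_grid)
    rx, ry = window.exterior_ring()
    return _pair_weights_bins(coords, s_grid, rx, ry, correction == "isotropic")


def k_from_pair_matrices(
    W: np.ndarray, B: np.ndarray, idx: np.ndarray, area: float, n_bins: int
) -> np.ndarray:
    """K hat on a point subset from precomputed pair matrices.

    K_hat(s_b) = (|A| / m^2) * sum of weights over within-subset ordered pairs
    with bin <= b, where m = len(idx).
    """
    m = len(idx)
    sub = np.ix_(idx, idx)
    counts = np.bincount(
        B[sub].ravel(), weights=W[sub].ravel(), minlength=n_bins + 1
    )[:n_bins]
    return np.cumsum(counts) * area / (m * m)


def _validate_s_grid(s_grid) -> np.ndarray:
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or s_grid.size == 0:
        raise ValueError("s_grid must be a non-empty 1-D array")
    if s_grid[0] <= 0 or np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be strictly increasing and start above 0")
    return s_grid


def k_function(
    pattern: PointPattern,
    s_grid: np.ndarray | None = None,
    correction: str = "isotropic",
) -> KEstimate:
    """Ripley's K function estimate on a distance grid.

    Parameters
    ----------
    pattern
        Point pattern with at least 2 points.
    s_grid
        Strictly increasing positive distances (meters). Defaults to 64
        equally spaced values up to 8000 m.
    correction
        ``"none"`` for the naive estimator, ``"isotropic"`` (default) for
        Ripley's isotropic edge correction.
    """
    if pattern.n < 2:
        raise EmptyPatternError("K function needs at least 2 points")
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = _validate_s_grid(s_grid)
    W, B = pair_weights_and_bins(pattern.coords, pattern.window, s_grid, correction)
    idx = np.arange(pattern.n)
    k_values = k_from_pair_matrices(W, B, idx, pattern.window.area, len(s_grid))
    return KEstimate(
        s_grid=s_grid,
        k_values=k_values,
        correction=correction,
        lambda_hat=intensity(pattern),
    )
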