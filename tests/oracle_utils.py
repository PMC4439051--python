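"""Independent brute-force oracles used to cross-check the estimators.

Everything here is deliberately naive and structurally different from the
library code: double loops, half-plane interval geometry, discretized
circles via shapely. Nothing imports the numba kernels under test.
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from shapely.geometry import Polygon


def k_naive_brute(coords: np.ndarray, area: float, s_grid: np.ndarray) -> np.ndarray:
    """Uncorrected K hat by an explicit double loop: (A/n^2) sum 1[d_ij <= s]."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    out = np.zeros(len(s_grid))
    for si, s in enumerate(s_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(
                    coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1]
                )
                if d <= s:
                    count += 1
        out[si] = area * count / (n * n)
    return out


def circle_fraction_convex(
    poly: Polygon, cx: float, cy: float, r: float
) -> float:
    """Fraction of circle circumference inside a CONVEX polygon, by exact
    half-plane angular intervals.

    A circle point c + r(cos t, sin t) lies inside iff for every edge the
    inward-normal constraint alpha_k + beta_k cos(t - phi_k) >= 0 holds; each
    constraint admits a closed-form arc. Arcs are combined by classifying
    midpoints of the subdivision induced by all arc endpoints, evaluating the
    constraints analytically.
    """
    verts = np.asarray(poly.exterior.coords)[:-1]
    # ensure counter-clockwise
    if poly.exterior.is_ccw is False:
        verts = verts[::-1]
    constraints = []  # (alpha, beta, phi)
    for k in range(len(verts)):
        ax, ay = verts[k]
        bx, by = verts[(k + 1) % len(verts)]
        # inward normal of CCW edge a->b is (-(by-ay), bx-ax)
        nx, ny = -(by - ay), bx - ax
        alpha = nx * (cx - ax) + ny * (cy - ay)
        beta = r * math.hypot(nx, ny)
        phi = math.atan2(ny, nx)
        constraints.append((alpha, beta, phi))

    # endpoints of the feasible arc of each constraint
    cuts = [0.0]
    for alpha, beta, phi in constraints:
        u = -alpha / beta
        if abs(u) < 1.0:
            g = math.acos(u)
            cuts.extend([(phi - g) % (2 * math.pi), (phi + g) % (2 * math.pi)])
    cuts = sorted(set(cuts))
    cuts.append(cuts[0] + 2 * math.pi)

    total = 0.0
    for a0, a1 in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a0 + a1)
        ok = all(
            alpha + beta * math.cos(mid - phi) >= 0 for alpha, beta, phi in constraints
        )
        if ok:
            total += a1 - a0
    return total / (2 * math.pi)


def circle_fraction_discretized(
    poly: Polygon, cx: float, cy: float, r: float, n_points: int = 4096
) -> float:
    """Fraction of circumference inside any polygon, by circle discretization."""
    t = np.linspace(0, 2 * math.pi, n_points, endpoint=False)
    pts = shapely.points(cx + r * np.cos(t), cy + r * np.sin(t))
    return float(np.mean(shapely.covers(poly, pts)))


def k_iso_brute_convex(
    coords: np.ndarray, poly: Polygon, s_grid: np.ndarray
) -> np.ndarray:
    """Isotropic-corrected K hat by double loop + half-plane weights (convex window)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    area = poly.area
    out = np.zeros(len(s_grid))
    for si, s in enumerate(s_grid):
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(
                    coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1]
                )
                if d <= s:
                    if d == 0:
                        acc += 1.0
                    else:
                        f = circle_fraction_convex(poly, coords[i, 0], coords[i, 1], d)
                        acc += 1.0 / f if f > 0 else 0.0
        out[si] = area * acc / (n * n)
    return out


def d_brute(coords, is_case, area, s_grid) -> np.ndarray:
    """Uncorrected D(s) from the naive per-group K hats."""
    return k_naive_brute(coords[is_case], area, s_grid) - k_naive_brute(
        coords[~is_case], area, s_grid
    )


def kernel_brute(n_in: int, N_in: int, n_out: int, M_out: int, full: bool) -> float:
    """The scan ranking kernel, written independently with explicit guards."""
    from fractions import Fraction

    risk_in = Fraction(n_in, N_in)
    risk_out = Fraction(n_out, M_out) if M_out > 0 else Fraction(0)
    if not (risk_in > risk_out and (M_out > 0 or n_out == 0)):
        return float("-inf")
    if M_out == 0:
        return float("-inf")

    def term(a, b):
        return 0.0 if a == 0 else a * math.log(a / b)

    v = term(n_in, N_in) + term(n_out, M_out)
    if full:
        C, T = n_in + n_out, N_in + M_out
        v += (
            term(N_in - n_in, N_in)
            + term(M_out - n_out, M_out)
            - term(C, T)
            - term(T - C, T)
        )
    return v


def window_sets_brute(coords, is_case, max_radius):
    """Distinct inside-sets per case center, enumerated over every (center, radius)."""
    coords = np.asarray(coords, dtype=float)
    out = {}
    for c in np.flatnonzero(is_case):
        d = np.hypot(coords[:, 0] - coords[c, 0], coords[:, 1] - coords[c, 1])
        sets = set()
        for r in d[d <= max_radius]:
            sets.add(frozenset(np.flatnonzero(d <= r).tolist()))
        out[int(c)] = sets
    return out


def max_loglr_brute(coords, is_case, max_radius, full=False):
    """Max kernel over every case-centered window, by exhaustive enumeration."""
    coords = np.asarray(coords, dtype=float)
    C = int(is_case.sum())
    T = len(coords)
    best = float("-inf")
    for c in np.flatnonzero(is_case):
        d = np.hypot(coords[:, 0] - coords[c, 0], coords[:, 1] - coords[c, 1])
        for r in np.unique(d[d <= max_radius]):
            inside = d <= r
            n_in = int(is_case[inside].sum())
            N_in = int(inside.sum())
            v = kernel_brute(n_in, N_in, C - n_in, T - N_in, full)
            best = max(best, v)
    return best
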