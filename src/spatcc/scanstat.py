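"""Purely spatial Bernoulli scan statistic for case-control point data.

Circular windows are centered at case locations, with the radius growing
through the sorted distances to every at-risk individual (cases and
controls), up to a maximum radius. For a window with n_in cases among N_in
at-risk individuals inside and n_out cases among M_out at-risk outside, the
default ranking kernel is

    log LR = n_in log(n_in / N_in) + n_out log(n_out / M_out)

evaluated only when the risk inside exceeds the risk outside
(n_in / N_in > n_out / M_out); other windows are not candidates. The full
Kulldorff Bernoulli log-likelihood ratio, which additionally carries the
non-case factors, is available as ``kernel="bernoulli"``; both kernels rank
a window against the constant-risk null.

The most likely cluster is the window maximizing the kernel. Its Monte Carlo
p-value compares the observed maximum against maxima recomputed under random
relabeling of the cases over all at-risk locations:

    p = (1 + #{replicates with max >= observed max}) / (n_replications + 1).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .dstat import CaseControlPattern

__all__ = [
    "Cluster",
    "ScanResult",
    "log_lr_kernel",
    "expected_cases",
    "enumerate_windows",
    "scan",
]


def log_lr_kernel(
    n_in: int, N_in: int, n_out: int, M_out: int, kernel: str = "paper"
) -> float:
    """Log likelihood-ratio kernel of one scanning window.

    Returns ``-inf`` when the window is not a candidate (risk inside not
    greater than risk outside). ``kernel="paper"`` uses the two-factor kernel
    above; ``kernel="bernoulli"`` the full Bernoulli log-likelihood ratio.
    Conventions: 0 * log(0/x) = 0.
    """
    if min(n_in, N_in, n_out, M_out) < 0:
        raise ValueError("counts must be nonnegative")
    if N_in == 0:
        raise ValueError("window must contain at least one at-risk individual")
    if n_in > N_in or n_out > M_out:
        raise ValueError("cases cannot exceed the at-risk count")
    if kernel == "paper":
        return _kernel_paper(n_in, N_in, n_out, M_out)
    if kernel == "bernoulli":
        return _kernel_bernoulli(n_in, N_in, n_out, M_out)
    raise ValueError("kernel must be 'paper' or 'bernoulli'")


@njit(cache=True)
def _kernel_paper(n_in: int, N_in: int, n_out: int, M_out: int) -> float:
    # indicator I(n_in/N_in > n_out/M_out) without division
    if n_in * M_out <= n_out * N_in:
        return -np.inf
    v = n_in * math.log(n_in / N_in)
    if n_out > 0:
        v += n_out * math.log(n_out / M_out)
    return v


@njit(cache=True)
def _xlogx_frac(a: int, b: int) -> float:
    # a * log(a / b), with 0 log 0 = 0
    if a == 0:
        return 0.0
    return a * math.log(a / b)


@njit(cache=True)
def _kernel_bernoulli(n_in: int, N_in: int, n_out: int, M_out: int) -> float:
    if n_in * M_out <= n_out * N_in:
        return -np.inf
    C = n_in + n_out
    T = N_in + M_out
    v = (
        _xlogx_frac(n_in, N_in)
        + _xlogx_frac(N_in - n_in, N_in)
        + _xlogx_frac(n_out, M_out)
        + _xlogx_frac(M_out - n_out, M_out)
        - _xlogx_frac(C, T)
        - _xlogx_frac(T - C, T)
    )
    return v


def expected_cases(C: int, N_in: int, N_total: int) -> float:
    """Expected cases inside a window under spatially constant risk.

    E = C * N_in / N_total, with C the total case count and N_in / N_total
    the fraction of the at-risk population inside the window.
    """
    if N_total <= 0:
        raise ValueError("total at-risk count must be positive")
    if not (0 <= N_in <= N_total):
        raise ValueError("N_in must be between 0 and N_total")
    if C < 0:
        raise ValueError("C must be nonnegative")
    return C * N_in / N_total


@dataclasses.dataclass(frozen=True)
class Cluster:
    """One reported scanning window."""

    center: tuple[float, float]
    center_index: int
    radius: float
    n_inside: int
    n_outside: int
    atrisk_inside: int
    atrisk_outside: int
    log_lr: float
    expected_cases: float
    p_value: Optional[float]
    member_indices: np.ndarray


@dataclasses.dataclass(frozen=True)
class ScanResult:
    """Ranked scan-statistic output; ``ranked`` may be empty if no window is a candidate."""

    total_cases: int
    total_atrisk: int
    ranked: list[Cluster]
    n_replications: int
    max_radius: float
    alpha: float
    seed: object
    kernel: str

    @property
    def primary(self) -> Optional[Cluster]:
        return self.ranked[0] if self.ranked else None


def enumerate_windows(
    data: CaseControlPattern, max_radius: float
) -> list[tuple[int, np.ndarray]]:
    """Candidate windows per case center.

    For every case location, the candidate radii are the sorted distinct
    distances from the center to every at-risk point within ``max_radius``
    (radius 0, the singleton window, always included). Each distinct
    point set inside a window is therefore represented exactly once per
    center.
    """
    if data.n_cases < 1:
        raise ValueError("need at least one case to center windows on")
    dmat = cdist(data.coords, data.coords)
    out = []
    for c in np.flatnonzero(data.is_case):
        d = dmat[c]
        radii = np.unique(d[d <= max_radius])
        out.append((int(c), radii))
    return out


@njit(cache=True)
def _scan_max(
    case: np.ndarray,
    center_ok: np.ndarray,
    indptr: np.ndarray,
    nbr: np.ndarray,
    ndist: np.ndarray,
    C: int,
    T: int,
    full_kernel: bool,
):
    """Max kernel over all candidate windows.

    Neighbors of each center are pre-sorted by distance; tied distances are
    absorbed together so each distinct inside-set is evaluated once. Ties in
    the kernel break toward smaller radius, then lower center index.
    Returns (stat, center, radius, n_in, N_in); stat = -inf if no candidate.
    """
    best = -np.inf
    bc = -1
    br = 0.0
    bn = 0
    bN = 0
    ncenters = indptr.shape[0] - 1
    for c in range(ncenters):
        if not (case[c] and center_ok[c]):
            continue
        n_in = 0
        N_in = 0
        i = indptr[c]
        end = indptr[c + 1]
        while i < end:
            r = ndist[i]
            j = i
            while j < end and ndist[j] == r:
                N_in += 1
                if case[nbr[j]]:
                    n_in += 1
                j += 1
            if full_kernel:
                v = _kernel_bernoulli(n_in, N_in, C - n_in, T - N_in)
            else:
                v = _kernel_paper(n_in, N_in, C - n_in, T - N_in)
            if v > best or (v == best and (r < br or (r == br and c < bc))):
                best = v
                bc = c
                br = r
                bn = n_in
                bN = N_in
            i = j
    return best, bc, br, bn, bN


@njit(cache=True)
def _best_per_center(
    case: np.ndarray,
    indptr: np.ndarray,
    nbr: np.ndarray,
    ndist: np.ndarray,
    C: int,
    T: int,
    full_kernel: bool,
):
    """Per-center best window (stat, radius, n_in, N_in); stat = -inf if none."""
    ncenters = indptr.shape[0] - 1
    stats = np.full(ncenters, -np.inf)
    radii = np.zeros(ncenters)
    nins = np.zeros(ncenters, dtype=np.int64)
    Nins = np.zeros(ncenters, dtype=np.int64)
    for c in range(ncenters):
        if not case[c]:
            continue
        n_in = 0
        N_in = 0
        i = indptr[c]
        end = indptr[c + 1]
        while i < end:
            r = ndist[i]
            j = i
            while j < end and ndist[j] == r:
                N_in += 1
                if case[nbr[j]]:
                    n_in += 1
                j += 1
            if full_kernel:
                v = _kernel_bernoulli(n_in, N_in, C - n_in, T - N_in)
            else:
                v = _kernel_paper(n_in, N_in, C - n_in, T - N_in)
            if v > stats[c] or (v == stats[c] and r < radii[c]):
                stats[c] = v
                radii[c] = r
                nins[c] = n_in
                Nins[c] = N_in
            i = j
    return stats, radii, nins, Nins


def _neighbor_csr(coords: np.ndarray, max_radius: float):
    """CSR arrays of, per point, its neighbors within max_radius sorted by distance."""
    dmat = cdist(coords, coords)
    n = coords.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    nbr_list = []
    dist_list = []
    for i in range(n):
        mask = dmat[i] <= max_radius
        idx = np.flatnonzero(mask)
        order = np.argsort(dmat[i, idx], kind="stable")
        nbr_list.append(idx[order])
        dist_list.append(dmat[i, idx[order]])
        indptr[i + 1] = indptr[i] + idx.size
    nbr = np.concatenate(nbr_list) if nbr_list else np.empty(0, dtype=np.int64)
    ndist = np.concatenate(dist_list) if dist_list else np.empty(0)
    return indptr, nbr.astype(np.int64), ndist.astype(np.float64), dmat


def scan(
    data: CaseControlPattern,
    max_radius: float = 5000.0,
    n_replications: int = 9999,
    alpha: float = 0.05,
    seed=None,
    kernel: str = "paper",
    max_reported: int = 10,
) -> ScanResult:
    """Run the spatial scan, rank clusters, and attach Monte Carlo p-values.

    Null replicates reassign the case labels uniformly at random over all
    at-risk locations, holding the number of cases fixed (constant-risk
    Bernoulli null), and recompute the maximum kernel with windows centered
    at the replicate's cases. Secondary clusters are reported greedily in
    descending kernel order, skipping windows that share any member with a
    higher-ranked reported cluster.
    """
    if data.n_cases < 1 or data.n_controls < 1:
        raise ValueError("scan needs at least one case and one control")
    if kernel not in ("paper", "bernoulli"):
        raise ValueError("kernel must be 'paper' or 'bernoulli'")
    if max_radius <= 0:
        raise ValueError("max_radius must be positive")
    full = kernel == "bernoulli"
    C = data.n_cases
    T = data.n
    case = data.is_case.astype(np.bool_)
    indptr, nbr, ndist, dmat = _neighbor_csr(data.coords, max_radius)
    all_ok = np.ones(T, dtype=np.bool_)

    stats, radii, nins, Nins = _best_per_center(case, indptr, nbr, ndist, C, T, full)
    t_obs = stats.max() if stats.size else -np.inf

    # null distribution of the maximum
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_replications)
    for r in range(n_replications):
        perm = rng.permutation(case)
        null_max[r], _, _, _, _ = _scan_max(perm, all_ok, indptr, nbr, ndist, C, T, full)

    ranked: list[Cluster] = []
    if np.isfinite(t_obs):
        order = sorted(
            np.flatnonzero(np.isfinite(stats)),
            key=lambda c: (-stats[c], radii[c], c),
        )
        used = np.zeros(T, dtype=bool)
        for c in order:
            members = np.flatnonzero(dmat[c] <= radii[c])
            if used[members].any():
                continue
            used[members] = True
            n_in = int(nins[c])
            N_in = int(Nins[c])
            p = float((1 + np.sum(null_max >= stats[c])) / (n_replications + 1))
            ranked.append(
                Cluster(
                    center=(float(data.coords[c, 0]), float(data.coords[c, 1])),
                    center_index=int(c),
                    radius=float(radii[c]),
                    n_inside=n_in,
                    n_outside=C - n_in,
                    atrisk_inside=N_in,
                    atrisk_outside=T - N_in,
                    log_lr=float(stats[c]),
                    expected_cases=expected_cases(C, N_in, T),
                    p_value=p,
                    member_indices=members,
                )
            )
            if len(ranked) >= max_reported:
                break

    return ScanResult(
        total_cases=C,
        total_atrisk=T,
        ranked=ranked,
        n_replications=n_replications,
        max_radius=max_radius,
        alpha=alpha,
        seed=seed,
        kernel=kernel,
    )
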