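"""Trajectory comparison statistics.

Resampling to a fixed index grid, cohort mean trajectories with a scalar
90% confidence-tube radius, dynamic time warping (DTW) distance, coverage
percentage against the tube, path length / navigation time, and the
occupancy trace maps (sqrt heat map on 5 m bins with a binary mask).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .environment import Arena

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import TrajectoryLog

__all__ = [
    "resample",
    "mean_trajectory",
    "ci_radius",
    "dtw_distance",
    "coverage_percentage",
    "path_length",
    "navigation_time",
    "TraceMap",
    "trace_maps",
    "binary_trace",
    "weighted_trace",
]

RESAMPLE_POINTS = 1000


def _as_path(path) -> np.ndarray:
    a = np.asarray(path, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("a path must be an (n, 2) array of plane points")
    return a


def resample(path, n: int = RESAMPLE_POINTS) -> np.ndarray:
    """Resample a path to ``n`` points uniform in normalized time index.

    Linear interpolation on the sample index (not arc length), preserving
    both endpoints, so paths recorded at different rates or durations become
    index-comparable.
    """
    a = _as_path(path)
    if len(a) < 2:
        raise ValueError("resampling requires at least 2 points")
    src = np.linspace(0.0, 1.0, len(a))
    dst = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(dst, src, a[:, k]) for k in (0, 1)])


def mean_trajectory(paths: Sequence, n: int = RESAMPLE_POINTS) -> np.ndarray:
    """Pointwise mean of the resampled paths (the cohort mean trajectory)."""
    if len(paths) == 0:
        raise ValueError("mean_trajectory requires at least one path")
    return np.mean([resample(p, n) for p in paths], axis=0)


def ci_radius(paths: Sequence, mean: np.ndarray | None = None) -> float:
    """Scalar 90% confidence-tube radius around the cohort mean.

    1.645 times the sample s.d. of the point-to-point distances between each
    resampled path and the mean, pooled over all paths and indices.
    """
    if len(paths) < 2:
        raise ValueError("ci_radius requires at least two paths")
    if mean is None:
        mean = mean_trajectory(paths)
    n = len(mean)
    d = np.concatenate([
        np.linalg.norm(resample(p, n) - mean, axis=1) for p in paths
    ])
    return 1.645 * float(np.std(d, ddof=1))


# ----------------------------------------------------------------- DTW ----

try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _dtw_matrix(a, b):  # pragma: no cover - exercised via dtw_distance
        n, m = a.shape[0], b.shape[0]
        D = np.full((n + 1, m + 1), np.inf)
        D[0, 0] = 0.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                dx = a[i - 1, 0] - b[j - 1, 0]
                dy = a[i - 1, 1] - b[j - 1, 1]
                c = math.sqrt(dx * dx + dy * dy)
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best
        return D

except ImportError:  # pragma: no cover
    def _dtw_matrix(a, b):
        n, m = a.shape[0], b.shape[0]
        D = np.full((n + 1, m + 1), np.inf)
        D[0, 0] = 0.0
        cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                D[i, j] = cost[i - 1, j - 1] + min(
                    D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
        return D


def _warp_path_length(D: np.ndarray) -> int:
    """Length of the optimal warping path by backtracking (diagonal-first)."""
    i, j = D.shape[0] - 1, D.shape[1] - 1
    steps = 1
    while i > 1 or j > 1:
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        steps += 1
    return steps


def dtw_distance(a, b, normalized: bool = False) -> float:
    """Classic DTW distance between two planar paths (metres).

    Euclidean local cost summed over the optimal monotone warping path with
    symmetric (diagonal/up/left) steps.  ``normalized`` divides by the
    optimal warping-path length, making values comparable across durations.
    """
    a = _as_path(a)
    b = _as_path(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("DTW is undefined for an empty path")
    D = _dtw_matrix(a, b)
    total = float(D[len(a), len(b)])
    if not normalized:
        return total
    return total / _warp_path_length(D)


# ----------------------------------------------------- coverage & basics ----

def _min_distance_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest point of the polyline."""
    p = _as_path(points)
    q = _as_path(poly)
    if len(q) == 1:
        return np.linalg.norm(p - q[0], axis=1)
    a = q[:-1]
    seg = q[1:] - a                                   # (m, 2)
    L2 = np.einsum("ij,ij->i", seg, seg)
    L2[L2 == 0.0] = 1.0
    out = np.empty(len(p))
    # chunk over points to bound the (chunk, m) temporaries
    step = max(1, int(2e6 / max(len(a), 1)))
    for s in range(0, len(p), step):
        pp = p[s:s + step]
        w = pp[:, None, :] - a[None, :, :]            # (c, m, 2)
        t = np.clip(np.einsum("cmk,mk->cm", w, seg) / L2, 0.0, 1.0)
        d = w - t[:, :, None] * seg[None, :, :]
        out[s:s + step] = np.sqrt(
            np.min(np.einsum("cmk,cmk->cm", d, d), axis=1))
    return out


def coverage_percentage(sim, mean, radius: float) -> float:
    """Percent of path points lying within ``radius`` of the mean polyline."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    d = _min_distance_to_polyline(_as_path(sim), _as_path(mean))
    return 100.0 * float(np.mean(d <= radius))


def path_length(path) -> float:
    """Total arc length of a path (m)."""
    a = _as_path(path)
    if len(a) < 2:
        raise ValueError("path length requires at least 2 samples")
    return float(np.sum(np.linalg.norm(np.diff(a, axis=0), axis=1)))


def navigation_time(log: "TrajectoryLog") -> float:
    """Duration covered by a log: (n_samples - 1) * sample interval (s)."""
    if log.n_samples < 2:
        raise ValueError("navigation time requires at least 2 samples")
    return (log.n_samples - 1) * log.dt


# ------------------------------------------------------------ trace maps ----

@dataclass
class TraceMap:
    """Square-root occupancy heat map on 5 m bins with a binary mask."""

    heat: np.ndarray          # (nx, ny)
    mask: np.ndarray          # (nx, ny) bool, heat > threshold
    bin_size: float
    threshold: float
    arena: Arena


def _bin_indices(path: np.ndarray, arena: Arena, bin_size: float) -> np.ndarray:
    nx = int(round(arena.width / bin_size))
    ny = int(round(arena.height / bin_size))
    if np.any(np.abs(path[:, 0]) > arena.half_width + 1e-9) or \
            np.any(np.abs(path[:, 1]) > arena.half_height + 1e-9):
        raise ValueError("path leaves the field; cannot bin")
    ix = np.clip(((path[:, 0] + arena.half_width) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((path[:, 1] + arena.half_height) / bin_size).astype(int), 0, ny - 1)
    return ix * ny + iy


def trace_maps(paths: Sequence, arena: Arena | None = None,
               bin_size: float = 5.0, threshold: float = 10.0) -> TraceMap:
    """Build the sqrt-occupancy heat map and its binary mask from a cohort.

    The per-bin heat is the square root of the number of trajectory points
    falling in that bin; the mask keeps bins whose *heat* exceeds the
    threshold, discarding bins only single trajectories pass through.
    """
    arena = arena or Arena()
    nx = int(round(arena.width / bin_size))
    ny = int(round(arena.height / bin_size))
    counts = np.zeros(nx * ny)
    for p in paths:
        np.add.at(counts, _bin_indices(_as_path(p), arena, bin_size), 1.0)
    heat = np.sqrt(counts).reshape(nx, ny)
    return TraceMap(heat=heat, mask=heat > threshold,
                    bin_size=bin_size, threshold=threshold, arena=arena)


def _visited(path, tmap: TraceMap) -> np.ndarray:
    return np.unique(_bin_indices(_as_path(path), tmap.arena, tmap.bin_size))


def binary_trace(path, tmap: TraceMap) -> float:
    """Fraction of the path's distinct visited bins that are mask-true."""
    vis = _visited(path, tmap)
    return float(np.mean(tmap.mask.ravel()[vis]))


def weighted_trace(path, tmap: TraceMap) -> float:
    """Mean heat over the path's distinct visited bins."""
    vis = _visited(path, tmap)
    return float(np.mean(tmap.heat.ravel()[vis]))
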