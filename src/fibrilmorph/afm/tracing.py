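"""Ridge tracing on flattened height maps.

Two modes mirror semi-automatic practice: a seeded minimal-cost ("live
wire") path between user-supplied endpoint pairs, and a fully automatic
mode (threshold + skeletonize + link) that needs no interaction.  Points
near path crossings are flagged excluded so their cross-sections are
skipped downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.spatial import cKDTree
from skimage.graph import route_through_array
from skimage.morphology import skeletonize

from ..errors import TracingError
from .heightmap import HeightMap

__all__ = ["RidgePath", "trace_ridges", "estimate_normals"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class RidgePath:
    """Ordered subpixel (row, col) coordinates along one fibril ridge."""

    points: np.ndarray
    excluded: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.points), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if len(self.excluded) != len(self.points):
            raise ValueError("excluded flags must match point count")
        if len(self.points) >= 2:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(steps > 2.0 + 1e-9):
                raise ValueError("consecutive ridge points more than 2 px apart")

    def __len__(self) -> int:
        return len(self.points)


def _skeleton_segments(mask: np.ndarray, min_length: int):
    """Split a skeleton into simple ordered paths, cut at branch points."""
    skel = skeletonize(mask)
    coords = set(zip(*np.nonzero(skel)))
    if not coords:
        return [], []

    def nbrs(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGHBORS if (p[0] + dr, p[1] + dc) in coords]

    degree = {p: len(nbrs(p)) for p in coords}
    branch_pts = [p for p, d in degree.items() if d >= 3]
    simple = coords - set(branch_pts)

    # traverse each residual simple component from an endpoint
    segments = []
    visited = set()
    for start in sorted(simple):
        if start in visited:
            continue
        local_nbrs = [q for q in nbrs(start) if q in simple]
        if len(local_nbrs) > 1:
            continue  # not an endpoint; reached later from one
        seg = [start]
        visited.add(start)
        cur, prev = start, None
        while True:
            nxt = [q for q in nbrs(cur) if q in simple and q != prev and q not in visited]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            seg.append(cur)
            visited.add(cur)
        if len(seg) >= min_length:
            segments.append(np.array(seg, dtype=float))
    # isolated loops (every pixel degree 2) are rare; walk them too
    for start in sorted(simple - visited):
        seg = [start]
        visited.add(start)
        cur, prev = start, None
        while True:
            nxt = [q for q in nbrs(cur) if q in simple and q != prev and q not in visited]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            seg.append(cur)
            visited.add(cur)
        if len(seg) >= min_length:
            segments.append(np.array(seg, dtype=float))
    return segments, branch_pts


def _refine_subpixel(points: np.ndarray, heights: np.ndarray) -> np.ndarray:
    """Shift each point toward the local ridge crest by a parabolic fit
    across the path, bounded to +/-0.5 px so spacing invariants hold."""
    from scipy.ndimage import map_coordinates

    pts = points.copy()
    if len(pts) < 5:
        return pts
    tangents = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    samples = []
    for off in (-1.0, 0.0, 1.0):
        c = pts + off * normals
        samples.append(
            map_coordinates(heights, [c[:, 0], c[:, 1]], order=1, mode="nearest")
        )
    z_m, z_0, z_p = samples
    denom = z_m - 2 * z_0 + z_p
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (z_m - z_p) / denom, 0.0)
    # only move toward a local crest (negative curvature), never off a flank
    shift = np.where(denom < 0, np.clip(shift, -0.5, 0.5), 0.0)
    return pts + shift[:, None] * normals


def trace_ridges(
    hmap: HeightMap,
    seeds: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
    threshold: float | None = None,
    min_length: int = 10,
    exclusion_radius: float | None = None,
    w1: float = 1.0,
    w2: float = 0.5,
    cost_cap: float | None = None,
    refine: bool = True,
) -> list[RidgePath]:
    """Trace fibril ridges on a flattened height map.

    With ``seeds`` (list of ((r0,c0),(r1,c1)) pairs) a minimal-cost path is
    found for each pair with cost ``w1*(height deficit) + w2*(gradient
    magnitude)``.  Without seeds, candidate ridge pixels are thresholded and
    skeletonized, then linked into simple paths cut at branch points.
    ``exclusion_radius`` (px; default 3x an estimated fibril half-width)
    flags points near another path or a skeleton junction as excluded.
    """
    z = hmap.heights
    if exclusion_radius is None:
        exclusion_radius = 3.0 * max(2.0, 10.0 / hmap.pixel_size)

    if seeds is not None:
        zmax, span = float(z.max()), float(np.ptp(z))
        span = span if span > 0 else 1.0
        gr, gc = np.gradient(z)
        gmag = np.hypot(gr, gc)
        gspan = gmag.max() if gmag.max() > 0 else 1.0
        cost = w1 * (zmax - z) / span + w2 * gmag / gspan + 1e-6
        paths = []
        for (p0, p1) in seeds:
            start = (int(round(p0[0])), int(round(p0[1])))
            end = (int(round(p1[0])), int(round(p1[1])))
            try:
                idx, total_cost = route_through_array(
                    cost, start, end, fully_connected=True, geometric=True
                )
            except ValueError as exc:
                raise TracingError(f"no path between {start} and {end}: {exc}") from exc
            if cost_cap is not None and total_cost > cost_cap:
                raise TracingError(
                    f"path cost {total_cost:.3g} exceeds cap {cost_cap:.3g}"
                )
            pts = np.array(idx, dtype=float)
            if refine:
                pts = _refine_subpixel(pts, z)
            paths.append(RidgePath(pts))
        _flag_crossings(paths, [], exclusion_radius)
        return paths

    # automatic mode
    if threshold is None:
        med = np.median(z)
        sigma = 1.4826 * np.median(np.abs(z - med))
        threshold = med + max(5.0 * sigma, 0.2 * max(z.max() - med, 0.0))
        if z.max() <= med or threshold <= med:
            warnings.warn("no ridge-like pixels found; returning empty result")
            return []
    mask = z > threshold
    if not mask.any():
        warnings.warn("no pixels above threshold; returning empty result")
        return []
    segments, branch_pts = _skeleton_segments(mask, min_length)
    paths = []
    for seg in segments:
        pts = _refine_subpixel(seg, z) if refine else seg
        paths.append(RidgePath(pts))
    _flag_crossings(paths, branch_pts, exclusion_radius)
    return paths


def _flag_crossings(paths: list[RidgePath], branch_pts, radius: float) -> None:
    """Flag points within ``radius`` px of another path or a junction."""
    if radius <= 0:
        return
    branch = np.array(branch_pts, dtype=float).reshape(-1, 2)
    branch_tree = cKDTree(branch) if len(branch) else None
    trees = [cKDTree(p.points) for p in paths]
    for i, path in enumerate(paths):
        flags = path.excluded
        if branch_tree is not None:
            d, _ = branch_tree.query(path.points)
            flags |= d <= radius
        for j, tree in enumerate(trees):
            if j == i:
                continue
            d, _ = tree.query(path.points)
            flags |= d <= radius
        path.excluded = flags


def estimate_normals(path: RidgePath, window: int = 5) -> np.ndarray:
    """Unit normals along a ridge path by median-filtered differencing.

    Finite differences of the path coordinates are median-filtered over a
    sliding window (robust to single-point outliers), normalized to unit
    tangents and rotated 90 degrees.
    """
    pts = path.points
    if len(pts) < 5:
        raise ValueError("path must have at least 5 points")
    d = np.diff(pts, axis=0)  # N-1 step vectors
    fd = np.column_stack(
        [median_filter(d[:, 0], size=window, mode="nearest"),
         median_filter(d[:, 1], size=window, mode="nearest")]
    )
    # per-point tangent: filtered step assigned to each point
    tangents = np.vstack([fd[0], 0.5 * (fd[1:] + fd[:-1]), fd[-1]])
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents /= norms
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return normals
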