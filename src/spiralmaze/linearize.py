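"""Skeleton fragmentation: from a tunnel mask to a signed curvilinear coordinate.

The corridor mask is skeletonized to a 1-px medial curve, the curve is cut
into short fragments at every crossing of a square grid, fragments are ordered
by walking outward from the fragment nearest the intersection of the plate
diagonals, and detections are assigned a signed along-path coordinate by
orthogonal projection onto the nearest fragment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

__all__ = [
    "PathSkeleton",
    "Fragment",
    "LinearPosition",
    "SkeletonError",
    "extract_skeleton",
    "fragment_and_order",
    "project_to_path",
    "skeleton_for_geometry",
]

_NEIGH = np.ones((3, 3), dtype=int)


class SkeletonError(ValueError):
    """Raised when the tunnel mask does not reduce to a single open curve."""


@dataclass(frozen=True)
class Fragment:
    index: int
    arm: int  # -1 left (negative s), +1 right, 0 for the center fragment
    s_begin: float  # mm, signed; s_begin < s_end
    s_end: float
    points: np.ndarray  # (k, 2) pixel coordinates (x, y)


@dataclass(frozen=True)
class LinearPosition:
    """A detection's place on the path: signed arc coordinate and offset."""

    s: float  # mm, signed
    perp: float  # mm, >= 0, perpendicular distance from the skeleton
    fragment: int


class PathSkeleton:
    """Ordered skeleton fragments carrying cumulative signed path distance.

    Parameters
    ----------
    points : (N, 2) float array
        Ordered skeleton pixels (x, y), traced tip to tip.
    s_mm : (N,) float array
        Signed arc-length coordinate of each pixel in mm, 0 at the center.
    fragment_of_point : (N,) int array
        Fragment index for every pixel.
    fragments : sequence of Fragment
    center : (x, y) px
    grid_spacing : px
    resolution : px per mm
    """

    def __init__(self, points, s_mm, fragment_of_point, fragments,
                 center, grid_spacing, resolution, s_chain_px=None):
        self.points = np.asarray(points, dtype=float)
        self.s_mm = np.asarray(s_mm, dtype=float)
        #: signed raw pixel-walk distance (orthogonal step 1, diagonal sqrt 2);
        #: kept alongside the de-staircased s_mm for diagnostics
        self.s_chain_px = (None if s_chain_px is None
                           else np.asarray(s_chain_px, dtype=float))
        self.fragment_of_point = np.asarray(fragment_of_point, dtype=int)
        self.fragments = list(fragments)
        self.center = tuple(float(c) for c in center)
        self.grid_spacing = float(grid_spacing)
        self.resolution = float(resolution)
        self._tree = cKDTree(self.points)

    @property
    def arm_lengths(self) -> tuple[float, float]:
        """(left, right) arm lengths in mm (both positive)."""
        return float(-self.s_mm.min()), float(self.s_mm.max())

    @property
    def total_length(self) -> float:
        return float(self.s_mm.max() - self.s_mm.min())

    def __len__(self) -> int:
        return len(self.fragments)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        rows = []
        for f in self.fragments:
            rows.append({
                "fragment": f.index,
                "arm": f.arm,
                "s_begin_mm": f.s_begin,
                "s_end_mm": f.s_end,
                "points": ";".join(f"{x:.2f},{y:.2f}" for x, y in f.points),
            })
        pd.DataFrame(rows).to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "center_px": list(self.center),
            "grid_spacing_px": self.grid_spacing,
            "resolution_px_per_mm": self.resolution,
            "n_fragments": len(self.fragments),
            "arm_lengths_mm": list(self.arm_lengths),
            "sign_convention": "arm leaving the center toward +x is positive",
        }

    def to_json_meta(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


# --------------------------------------------------------------------------
# skeleton extraction


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGH, mode="constant") - skel


def _branch_points(skel: np.ndarray) -> np.ndarray:
    """True branch points by crossing number: pixels whose 8-neighborhood
    ring shows three or more 0->1 transitions.  Plain degree counting flags
    harmless L-corners of an 8-connected curve as junctions; the crossing
    number does not."""
    p = np.pad(skel, 1)
    ring = [p[1 + dr:p.shape[0] - 1 + dr, 1 + dc:p.shape[1] - 1 + dc]
            for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, 1),
                           (1, 1), (1, 0), (1, -1), (0, -1))]
    trans = np.zeros(skel.shape, dtype=int)
    for a, b in zip(ring, ring[1:] + ring[:1]):
        trans += (~a) & b
    return skel & (trans >= 3)


def _prune_spurs(skel: np.ndarray, max_spur: int) -> np.ndarray:
    """Remove side branches shorter than ``max_spur`` pixels, repeatedly,
    until the curve has exactly two endpoints or nothing changes."""
    skel = skel.copy()
    for _ in range(64):
        deg = _neighbor_count(skel)
        endpoints = np.argwhere(skel & (deg == 1))
        branch = _branch_points(skel)
        if len(endpoints) <= 2 and not branch.any():
            break
        removed_any = False
        for ep in endpoints:
            path = [tuple(ep)]
            seen = {tuple(ep)}
            cur = tuple(ep)
            is_spur = False
            for _step in range(max_spur):
                r, c = cur
                nxt = None
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1]
                                and skel[rr, cc] and (rr, cc) not in seen):
                            if branch[rr, cc]:
                                is_spur = True
                                nxt = None
                                break
                            nxt = (rr, cc)
                    if is_spur:
                        break
                if is_spur or nxt is None:
                    break
                path.append(nxt)
                seen.add(nxt)
                cur = nxt
            if is_spur:
                for r, c in path:
                    skel[r, c] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def extract_skeleton(tunnel_mask: np.ndarray, prune_px: int | None = None) -> np.ndarray:
    """Skeletonize a corridor mask to a 1-px-wide open medial curve.

    Returns a boolean image.  Spurs shorter than ``prune_px`` (default 20)
    are removed; the result must have exactly two endpoints (the tunnel tips).

    Raises
    ------
    SkeletonError
        If the mask is empty, not a single connected component, or does not
        reduce to a simple open curve.
    """
    mask = np.asarray(tunnel_mask, dtype=bool)
    if not mask.any():
        raise SkeletonError("tunnel mask is empty")
    _, n_comp = ndimage.label(mask, structure=_NEIGH)
    if n_comp != 1:
        raise SkeletonError(f"tunnel mask has {n_comp} connected components, expected 1")
    skel = skeletonize(mask)
    skel = _prune_spurs(skel, int(prune_px) if prune_px else 20)
    deg = _neighbor_count(skel)
    n_end = int(np.sum(skel & (deg == 1)))
    if n_end != 2:
        raise SkeletonError(
            f"skeleton has {n_end} endpoints after pruning, expected 2 "
            "(increase prune_px or check the mask)"
        )
    return _extend_to_tips(skel, mask)


def _extend_to_tips(skel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both skeleton endpoints along the local tangent to the mask
    boundary: thinning erodes roughly half the corridor width at each tip,
    which would truncate arc coordinates near the tunnel ends."""
    skel = skel.copy()
    h, w = skel.shape
    deg = _neighbor_count(skel)
    for ep in np.argwhere(skel & (deg == 1)):
        # walk a few pixels inward to estimate the tip tangent
        prev = {tuple(ep)}
        cur = tuple(ep)
        for _ in range(6):
            nxt = None
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = cur[0] + dr, cur[1] + dc
                    if (0 <= rr < h and 0 <= cc < w and skel[rr, cc]
                            and (rr, cc) not in prev):
                        nxt = (rr, cc)
                        break
                if nxt:
                    break
            if nxt is None:
                break
            prev.add(nxt)
            cur = nxt
        d = np.asarray(ep, dtype=float) - np.asarray(cur, dtype=float)
        norm = np.hypot(*d)
        if norm == 0:
            continue
        d /= norm
        p = np.asarray(ep, dtype=float)
        for _ in range(int(4 * norm) + 64):
            p = p + d * 0.7
            rr, cc = int(round(p[0])), int(round(p[1]))
            if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                break
            skel[rr, cc] = True
    return skel


def _trace(skel: np.ndarray) -> np.ndarray:
    """Order the skeleton pixels from one endpoint to the other.

    Returns an (N, 2) array of (row, col).  Greedy walk preferring orthogonal
    steps; fails if more than a handful of pixels cannot be reached.
    """
    deg = _neighbor_count(skel)
    ends = np.argwhere(skel & (deg == 1))
    if len(ends) != 2:
        raise SkeletonError(f"cannot trace skeleton with {len(ends)} endpoints")
    h, w = skel.shape
    visited = np.zeros_like(skel)
    cur = tuple(ends[0])
    path = [cur]
    visited[cur] = True
    total = int(skel.sum())
    while True:
        r, c = cur
        best = None
        best_d = 9
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and skel[rr, cc] and not visited[rr, cc]:
                    d = dr * dr + dc * dc
                    if d < best_d:
                        best_d = d
                        best = (rr, cc)
        if best is None:
            break
        visited[best] = True
        path.append(best)
        cur = best
    if len(path) < 0.98 * total:
        raise SkeletonError(
            f"skeleton trace covered {len(path)}/{total} pixels; curve is not simple"
        )
    return np.asarray(path)


# --------------------------------------------------------------------------
# fragmentation and ordering


def fragment_and_order(
    skeleton: np.ndarray,
    grid_spacing: float,
    plate_corners: Sequence[Sequence[float]] | None = None,
    resolution: float = 1.0,
    positive_toward: str = "+x",
    smooth_window: int = 5,
) -> PathSkeleton:
    """Cut the skeleton at square-grid crossings and order fragments outward
    from the center found by the plate diagonals.

    Parameters
    ----------
    skeleton : bool image
        Output of :func:`extract_skeleton`.
    grid_spacing : float, px
        Side of the cutting grid (>= 2).
    plate_corners : four (x, y) px points, optional
        Corners of the plate (or of the mask bounding box if omitted); the
        intersection of the diagonals defines the spiral center.
    resolution : px per mm
        Used to express arc positions in mm.
    positive_toward : "+x" or "-x"
        Which departure direction from the center carries positive s.
    """
    if grid_spacing < 2:
        raise ValueError("grid_spacing must be >= 2 px")
    path_rc = _trace(skeleton)
    raw = path_rc[:, ::-1].astype(float)  # (x, y)

    # raw pixel-walk distance (1 per orthogonal step, sqrt2 per diagonal)
    chain_steps = np.hypot(*np.diff(raw, axis=0).T)
    chain = np.concatenate([[0.0], np.cumsum(chain_steps)])

    # the raw 8-connected chain overestimates smooth-curve length by up to
    # ~5-8 % (staircase bias); a short moving average of the pixel trace
    # suppresses it so arc positions track true millimetres
    pts = ndimage.uniform_filter1d(raw, size=smooth_window, axis=0, mode="nearest")
    steps = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])

    if plate_corners is None:
        ys, xs = np.nonzero(skeleton)
        cx, cy = (xs.min() + xs.max()) / 2.0, (ys.min() + ys.max()) / 2.0
    else:
        corners = np.asarray(plate_corners, dtype=float)
        cx, cy = corners.mean(axis=0)  # diagonal intersection of a rectangle

    i0 = int(np.argmin(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)))
    s_px = cum - cum[i0]
    chain_px = chain - chain[i0]

    # positive arm = the one departing the center toward +x (or -x)
    probe = min(i0 + max(int(grid_spacing), 4), len(pts) - 1)
    probe_back = max(i0 - max(int(grid_spacing), 4), 0)
    dx_fwd = pts[probe, 0] - pts[i0, 0]
    dx_back = pts[probe_back, 0] - pts[i0, 0]
    want = 1.0 if positive_toward == "+x" else -1.0
    if (dx_fwd - dx_back) * want < 0:
        pts = pts[::-1]
        s_px = -s_px[::-1]
        chain_px = -chain_px[::-1]
        i0 = len(pts) - 1 - i0

    # cut where the grid cell index changes
    cell = np.floor(pts / grid_spacing).astype(int)
    change = np.any(np.diff(cell, axis=0) != 0, axis=1)
    frag_idx = np.concatenate([[0], np.cumsum(change)]).astype(int)

    s_mm = s_px / resolution
    fragments = []
    center_frag = int(frag_idx[i0])
    n_frag = int(frag_idx.max()) + 1
    first = np.searchsorted(frag_idx, np.arange(n_frag + 1))
    for k in range(n_frag):
        m = frag_idx == k
        fs = s_mm[m]
        arm = 0 if k == center_frag else (1 if fs.mean() > 0 else -1)
        # half-open spans [s_begin, s_end): s_end is the next fragment's
        # first arc position, so spans tile the path without gaps
        s_end = s_mm[first[k + 1]] if k + 1 < n_frag else float(fs.max())
        fragments.append(Fragment(
            index=k, arm=arm,
            s_begin=float(fs.min()), s_end=float(s_end),
            points=pts[m].copy(),
        ))

    return PathSkeleton(pts, s_mm, frag_idx, fragments,
                        (cx, cy), grid_spacing, resolution,
                        s_chain_px=chain_px)


def skeleton_for_geometry(geometry, resolution: float,
                          grid_spacing: float | None = None,
                          prune_px: int | None = None) -> PathSkeleton:
    """Convenience: rasterize a maze geometry, skeletonize and fragment it.

    Default grid spacing is half the corridor width in px (sub-corridor
    resolution); spurs are pruned below twice the grid spacing.
    """
    from .geometry import render_tunnel_mask

    if grid_spacing is None:
        grid_spacing = geometry.path_width * resolution / 2.0
    if prune_px is None:
        prune_px = int(2 * grid_spacing)
    mask = render_tunnel_mask(geometry, resolution)
    skel = extract_skeleton(mask, prune_px=prune_px)
    h, w = mask.shape
    corners = [(0, 0), (w - 1, 0), (w - 1, h - 1), (0, h - 1)]
    return fragment_and_order(skel, grid_spacing, plate_corners=corners,
                              resolution=resolution)


# --------------------------------------------------------------------------
# orthogonal projection


def _project_points(points_px: np.ndarray, path: PathSkeleton):
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    _, idx = path._tree.query(pts)
    P = path.points
    S = path.s_mm
    n = len(P)

    best_s = np.empty(len(pts))
    best_d = np.full(len(pts), np.inf)
    best_i = idx.copy()
    for off in (-1, 0):
        a = np.clip(idx + off, 0, n - 2)
        b = a + 1
        pa, pb = P[a], P[b]
        ab = pb - pa
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", pts - pa, ab) / denom, 0.0, 1.0)
        foot = pa + t[:, None] * ab
        d = np.hypot(*(pts - foot).T)
        s = S[a] + t * (S[b] - S[a])
        # strictly better, or equally good but smaller |s| (deterministic tie-break)
        better = (d < best_d - 1e-12) | ((np.abs(d - best_d) <= 1e-12)
                                         & (np.abs(s) < np.abs(best_s)))
        best_d = np.where(better, d, best_d)
        best_s = np.where(better, s, best_s)
        best_i = np.where(better, a, best_i)
    frag = path.fragment_of_point[best_i]
    return best_s, best_d / path.resolution, frag


def project_to_path(centroid, path: PathSkeleton, quantize: bool = False):
    """Orthogonally project pixel coordinates onto the path skeleton.

    Parameters
    ----------
    centroid : (x, y) or (N, 2) pixel coordinates
    path : PathSkeleton
    quantize : bool
        If True, return the fragment's central arc position (the coarse
        "fragment distance" variant) instead of the exact projection.

    Returns
    -------
    LinearPosition for a single point, or a DataFrame (s_mm, perp_mm,
    fragment) for an array of points.
    """
    arr = np.asarray(centroid, dtype=float)
    single = arr.ndim == 1
    s, perp, frag = _project_points(arr, path)
    if quantize:
        mids = np.array([(f.s_begin + f.s_end) / 2.0 for f in path.fragments])
        s = mids[frag]
    if single:
        return LinearPosition(float(s[0]), float(perp[0]), int(frag[0]))
    return pd.DataFrame({"s_mm": s, "perp_mm": perp, "fragment": frag})
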