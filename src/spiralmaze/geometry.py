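"""Double-spiral maze geometry: centerline, wall polygons, rasterization, occlusion.

The maze is a long corridor wrapped into two interleaved Archimedean spirals
joined at the plate center by a point-symmetric S-curve, so that individuals
introduced at the center experience identical topology whether they disperse
left or right.  All physical coordinates are millimetres, origin at the plate
center, y up.  Raster masks use 0-based pixel indices with pixel centers at
(index + 0.5) / resolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import (
    LineString,
    MultiPolygon,
    Polygon,
    box,
    mapping,
    shape,
)
from shapely.ops import unary_union

__all__ = [
    "MazeGeometry",
    "OcclusionResult",
    "GeometryError",
    "generate_double_spiral",
    "default_maze",
    "render_tunnel_mask",
    "occluded_floor_fraction",
    "mm_to_px",
    "px_to_mm",
    "DEFAULT_PROFILE",
]

LEVOGYROUS = "levogyrous"
DEXTROGYROUS = "dextrogyrous"

#: Frozen default build profile.  plate and corridor dimensions follow the
#: physical device (440 x 330 mm plate, 10 mm wide corridor, 5 mm walls);
#: wall_width and n_turns_per_arm were calibrated once so that the generated
#: centerline is 5.75 m long, and are not tuned per run.
DEFAULT_PROFILE = {
    "plate_width": 440.0,
    "plate_height": 330.0,
    "path_width": 10.0,
    "wall_width": 2.0,
    "wall_height": 5.0,
    "n_turns_per_arm": 4.74,
    "handedness": LEVOGYROUS,
}

#: chord length (mm) used when sampling curves; small versus every curvature
#: radius in the maze, so polyline arc length is accurate to < 0.01 %.
_CHORD_MM = 0.2


class GeometryError(ValueError):
    """Raised when a requested maze geometry is infeasible."""


@dataclass(frozen=True)
class MazeGeometry:
    """A double-spiral maze: plate, corridor centerline and wall polygons.

    The centerline is an ordered polyline parameterized by signed arc length
    ``s`` with ``s = 0`` at the introduction point (plate center); the arm
    leaving the center toward +x carries positive s.
    """

    plate_width: float
    plate_height: float
    path_width: float
    wall_width: float
    wall_height: float
    n_turns_per_arm: float
    handedness: str
    centerline: np.ndarray  # (N, 2) mm, ordered from s_min to s_max
    s: np.ndarray  # (N,) signed arc length, mm
    wall_polygons: tuple = field(default=())

    @property
    def arc_length(self) -> float:
        """Total centerline length (mm)."""
        return float(self.s[-1] - self.s[0])

    @property
    def arm_lengths(self) -> tuple[float, float]:
        """(negative-arm, positive-arm) lengths in mm."""
        return float(-self.s[0]), float(self.s[-1])

    @property
    def plate_polygon(self) -> Polygon:
        w, h = self.plate_width / 2.0, self.plate_height / 2.0
        return box(-w, -h, w, h)

    @property
    def tunnel_polygon(self) -> Polygon:
        """Corridor floor outline: the centerline buffered by half the path width."""
        line = LineString(self.centerline)
        return line.buffer(self.path_width / 2.0, quad_segs=16)

    @property
    def introduction_point(self) -> np.ndarray:
        i = int(np.argmin(np.abs(self.s)))
        return self.centerline[i].copy()

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Embed signed arc positions to 2-D (mm) by interpolating the centerline."""
        x = np.interp(s, self.s, self.centerline[:, 0])
        y = np.interp(s, self.s, self.centerline[:, 1])
        return np.stack(np.broadcast_arrays(x, y), axis=-1)

    def normal_at(self, s: float | np.ndarray) -> np.ndarray:
        """Unit normal of the centerline at arc position(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        ds = 0.5
        p0 = self.point_at(np.clip(s - ds, self.s[0], self.s[-1]))
        p1 = self.point_at(np.clip(s + ds, self.s[0], self.s[-1]))
        t = p1 - p0
        norm = np.hypot(t[:, 0], t[:, 1])
        norm[norm == 0] = 1.0
        t /= norm[:, None]
        return np.stack([-t[:, 1], t[:, 0]], axis=-1)

    def mirrored(self) -> "MazeGeometry":
        """Mirror about the y axis, flipping handedness; arc lengths unchanged."""
        pts = self.centerline * np.array([-1.0, 1.0])
        walls = tuple(affinity.scale(p, xfact=-1, yfact=1, origin=(0, 0))
                      for p in self.wall_polygons)
        other = DEXTROGYROUS if self.handedness == LEVOGYROUS else LEVOGYROUS
        # reverse so that s still increases along the arm leaving toward +x
        return replace(self, centerline=pts[::-1].copy(), s=(-self.s[::-1]).copy(),
                       handedness=other, wall_polygons=walls)

    # ------------------------------------------------------------------ I/O

    def to_json(self, path=None) -> str:
        doc = {
            "plate_width": self.plate_width,
            "plate_height": self.plate_height,
            "path_width": self.path_width,
            "wall_width": self.wall_width,
            "wall_height": self.wall_height,
            "n_turns_per_arm": self.n_turns_per_arm,
            "handedness": self.handedness,
            "centerline": self.centerline.tolist(),
            "s": self.s.tolist(),
            "wall_polygons": [mapping(p) for p in self.wall_polygons],
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MazeGeometry":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            try:
                doc = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    doc = json.load(fh)
        return cls(
            plate_width=doc["plate_width"],
            plate_height=doc["plate_height"],
            path_width=doc["path_width"],
            wall_width=doc["wall_width"],
            wall_height=doc["wall_height"],
            n_turns_per_arm=doc["n_turns_per_arm"],
            handedness=doc["handedness"],
            centerline=np.asarray(doc["centerline"], dtype=float),
            s=np.asarray(doc["s"], dtype=float),
            wall_polygons=tuple(shape(p) for p in doc["wall_polygons"]),
        )

    def to_svg(self, path) -> None:
        """Write plate outline and wall polygons as an SVG (mm user units),
        suitable as a laser-cutting template."""
        w, h = self.plate_width, self.plate_height

        def ring_to_path(coords):
            pts = " L ".join(f"{x + w / 2:.3f},{h / 2 - y:.3f}" for x, y in coords)
            return f"M {pts} Z"

        paths = []
        for poly in self.wall_polygons:
            polys = poly.geoms if isinstance(poly, MultiPolygon) else [poly]
            for p in polys:
                d = ring_to_path(p.exterior.coords)
                for hole in p.interiors:
                    d += " " + ring_to_path(hole.coords)
                paths.append(
                    f'<path d="{d}" fill="#888" fill-rule="evenodd" '
                    f'stroke="black" stroke-width="0.2"/>'
                )
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}mm" height="{h}mm" '
            f'viewBox="0 0 {w} {h}">\n'
            f'<rect x="0" y="0" width="{w}" height="{h}" fill="none" '
            f'stroke="black" stroke-width="0.2"/>\n' + "\n".join(paths) + "\n</svg>\n"
        )
        with open(path, "w") as fh:
            fh.write(svg)


# --------------------------------------------------------------------------
# construction


def _spiral_arm(r0: float, c: float, n_turns: float) -> np.ndarray:
    """CCW Archimedean arm r = r0 + c*phi from (r0, 0) outward, fine polyline."""
    phi_max = 2.0 * math.pi * n_turns
    if phi_max <= 0:
        return np.empty((0, 2))
    # angular step keeping chords below _CHORD_MM at the smallest radius
    n = max(int(phi_max * (r0 + c * phi_max) / _CHORD_MM), 8)
    phi = np.linspace(0.0, phi_max, n)
    r = r0 + c * phi
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)


def _s_curve_half(r0: float) -> np.ndarray:
    """Half of the central S: semicircle from the origin to (r0, 0) dipping into
    y < 0, tangent-matched to a CCW spiral departing at (r0, 0)."""
    n = max(int(math.pi * r0 / 2.0 / _CHORD_MM), 8)
    u = np.linspace(0.0, 1.0, n)
    return (r0 / 2.0) * np.stack([1.0 - np.cos(np.pi * u), -np.sin(np.pi * u)], axis=-1)


def _cumulative_length(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def generate_double_spiral(
    plate_width: float = DEFAULT_PROFILE["plate_width"],
    plate_height: float = DEFAULT_PROFILE["plate_height"],
    path_width: float = DEFAULT_PROFILE["path_width"],
    wall_width: float = DEFAULT_PROFILE["wall_width"],
    n_turns_per_arm: float = DEFAULT_PROFILE["n_turns_per_arm"],
    handedness: str = LEVOGYROUS,
    wall_height: float = DEFAULT_PROFILE["wall_height"],
) -> MazeGeometry:
    """Generate a connected two-armed spiral maze filling the plate.

    Two interleaved Archimedean spirals (constant centerline pitch
    ``path_width + wall_width`` between adjacent corridors) are joined at the
    center by a point-symmetric S-curve; the whole centerline is stretched
    along the plate's long axis so the spiral envelope matches the plate
    aspect, and walls are the plate material left between corridors.

    Raises
    ------
    GeometryError
        If the requested number of turns does not fit inside the plate.
    """
    if path_width <= 0 or wall_width <= 0:
        raise GeometryError("path_width and wall_width must be positive")
    if n_turns_per_arm < 0:
        raise GeometryError("n_turns_per_arm must be >= 0")
    if handedness not in (LEVOGYROUS, DEXTROGYROUS):
        raise GeometryError(f"unknown handedness {handedness!r}")

    d = path_width + wall_width  # radial spacing between adjacent corridors
    c = d / math.pi  # per-arm radial growth rate (interleaving halves the pitch)
    r0 = 2.0 * d  # inner radius: keeps the S-curve clear of the first winding

    half_s = _s_curve_half(r0)
    arm = _spiral_arm(r0, c, n_turns_per_arm)
    pos = np.concatenate([half_s, arm[1:]]) if len(arm) else half_s
    neg = -pos[::-1]  # point reflection: the other arm
    center_pts = np.concatenate([neg[:-1], pos])

    # stretch along the longer plate axis to fill a non-square plate
    short = min(plate_width, plate_height)
    stretch = max(plate_width, plate_height) / short
    sx, sy = (stretch, 1.0) if plate_width >= plate_height else (1.0, stretch)
    center_pts = center_pts * np.array([sx, sy])

    r_max = r0 + c * 2.0 * math.pi * n_turns_per_arm
    margin = path_width / 2.0 + wall_width
    if 2.0 * (r_max + margin) > short:
        raise GeometryError(
            f"{n_turns_per_arm} turns per arm (envelope radius {r_max:.1f} mm) "
            f"do not fit in a {plate_width:.0f} x {plate_height:.0f} mm plate"
        )

    if handedness == DEXTROGYROUS:
        center_pts = (center_pts * np.array([-1.0, 1.0]))[::-1]

    cum = _cumulative_length(center_pts)
    i0 = int(np.argmin(np.hypot(center_pts[:, 0], center_pts[:, 1])))
    s = cum - cum[i0]

    geom = MazeGeometry(
        plate_width=plate_width,
        plate_height=plate_height,
        path_width=path_width,
        wall_width=wall_width,
        wall_height=wall_height,
        n_turns_per_arm=n_turns_per_arm,
        handedness=handedness,
        centerline=center_pts,
        s=s,
    )
    walls = geom.plate_polygon.difference(geom.tunnel_polygon)
    if isinstance(walls, MultiPolygon):
        wall_tuple = tuple(walls.geoms)
    else:
        wall_tuple = (walls,)
    return replace(geom, wall_polygons=wall_tuple)


def default_maze(handedness: str = LEVOGYROUS) -> MazeGeometry:
    """The frozen default build profile (5.75 m corridor in a 440 x 330 mm plate)."""
    prof = dict(DEFAULT_PROFILE)
    prof["handedness"] = handedness
    return generate_double_spiral(**prof)


# --------------------------------------------------------------------------
# rasterization


def mm_to_px(points_mm: np.ndarray, resolution: float,
             plate_width: float, plate_height: float) -> np.ndarray:
    """Map mm coordinates (origin at plate center, y up) to (x, y) pixel
    coordinates (origin top-left, y down)."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    x = (pts[:, 0] + plate_width / 2.0) * resolution - 0.5
    y = (plate_height / 2.0 - pts[:, 1]) * resolution - 0.5
    return np.stack([x, y], axis=-1)


def px_to_mm(points_px: np.ndarray, resolution: float,
             plate_width: float, plate_height: float) -> np.ndarray:
    """Inverse of :func:`mm_to_px`."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    x = (pts[:, 0] + 0.5) / resolution - plate_width / 2.0
    y = plate_height / 2.0 - (pts[:, 1] + 0.5) / resolution
    return np.stack([x, y], axis=-1)


def render_tunnel_mask(geometry: MazeGeometry, resolution: float) -> np.ndarray:
    """Rasterize the corridor floor at ``resolution`` px/mm.

    Returns a boolean image (rows = plate_height * resolution) that is True on
    the tunnel floor.  The corridor is recovered as the set of pixels within
    path_width/2 of the centerline, computed with an exact Euclidean distance
    transform, so the mask is a single 8-connected tube.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    h = int(round(geometry.plate_height * resolution))
    w = int(round(geometry.plate_width * resolution))
    # burn a 1-px polyline of the centerline, then threshold the EDT
    line = np.zeros((h, w), dtype=bool)
    pts = mm_to_px(geometry.centerline, resolution,
                   geometry.plate_width, geometry.plate_height)
    # densify so consecutive samples are < 1 px apart
    seg = np.hypot(*np.diff(pts, axis=0).T)
    n_extra = np.maximum(seg.astype(int), 1)
    dense = [pts[:1]]
    for i, k in enumerate(n_extra):
        t = np.linspace(0, 1, k + 1)[1:, None]
        dense.append(pts[i] * (1 - t) + pts[i + 1] * t)
    dense = np.concatenate(dense)
    ij = np.round(dense[:, ::-1]).astype(int)
    keep = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
    line[ij[keep, 0], ij[keep, 1]] = True
    dist = ndimage.distance_transform_edt(~line)
    half_w = geometry.path_width / 2.0 * resolution
    mask = dist <= half_w

    # flat tunnel ends: cut the round caps the distance transform grows
    # beyond the two centerline tips
    for end, inner in ((pts[0], pts[1]), (pts[-1], pts[-2])):
        tangent = end - inner
        norm = np.hypot(*tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        r = int(np.ceil(half_w)) + 2
        x0, y0 = int(round(end[0])), int(round(end[1]))
        xa, xb = max(x0 - r, 0), min(x0 + r + 1, w)
        ya, yb = max(y0 - r, 0), min(y0 + r + 1, h)
        if xa >= xb or ya >= yb:
            continue
        yy, xx = np.mgrid[ya:yb, xa:xb]
        beyond = ((xx - end[0]) * tangent[0] + (yy - end[1]) * tangent[1]) > 0.5
        mask[ya:yb, xa:xb] &= ~beyond
    return mask


# --------------------------------------------------------------------------
# camera occlusion


@dataclass(frozen=True)
class OcclusionResult:
    """Fraction of tunnel floor hidden from the camera by wall tops."""

    occluded_fraction: float
    monitored_fraction: float
    bin_centers_s: np.ndarray  # mm, |s| bin midpoints
    bin_occluded_fraction: np.ndarray
    correlation_with_distance: float  # Pearson r of per-bin occlusion vs |s|


def occluded_floor_fraction(
    geometry: MazeGeometry,
    wall_height: float | None = None,
    camera_height: float = 700.0,
    optical_axis: Sequence[float] = (0.0, 0.0),
    n_bins: int = 20,
) -> OcclusionResult:
    """Fraction of corridor floor shadowed by wall tops under central projection.

    A camera at ``camera_height`` above the floor sees past a wall of height
    ``h`` only beyond the projection of its top edge: material at lateral
    distance r from the optical axis hides a floor strip of width
    ``r * h / (camera_height - h)`` on its far side.  Equivalently the hidden
    region is the union of the wall footprint scaled about the axis by every
    factor in [1, camera_height / (camera_height - h)], intersected with the
    corridor floor.  Also reports per-|s|-bin occlusion and its correlation
    with distance from the introduction point.
    """
    h = geometry.wall_height if wall_height is None else float(wall_height)
    if camera_height <= h:
        raise GeometryError("camera_height must exceed wall_height")
    floor = geometry.tunnel_polygon
    if h <= 0:
        edges = np.linspace(0, max(map(abs, geometry.arm_lengths)), n_bins + 1)
        mids = 0.5 * (edges[1:] + edges[:-1])
        return OcclusionResult(0.0, 1.0, mids, np.zeros(n_bins), 0.0)

    k = camera_height / (camera_height - h)
    walls = unary_union(list(geometry.wall_polygons))
    # union of scaled copies; step chosen so successive displacements stay
    # below the wall thickness and leave no gaps
    r_max = max(geometry.plate_width, geometry.plate_height)
    step = geometry.wall_width / (2.0 * r_max)
    n_scales = max(int(math.ceil((k - 1.0) / step)) + 1, 2)
    copies = [
        affinity.scale(walls, xfact=t, yfact=t, origin=tuple(optical_axis) + (0,))
        for t in np.linspace(1.0, k, n_scales)
    ]
    shadow = unary_union(copies)
    occluded = shadow.intersection(floor)
    frac = occluded.area / floor.area

    # per-bin occlusion along |s|
    arm_len = max(map(abs, geometry.arm_lengths))
    edges = np.linspace(0.0, arm_len, n_bins + 1)
    mids = 0.5 * (edges[1:] + edges[:-1])
    per_bin = np.zeros(n_bins)
    half_w = geometry.path_width / 2.0
    for b in range(n_bins):
        pieces = []
        for sgn in (-1.0, 1.0):
            lo, hi = sgn * edges[b], sgn * edges[b + 1]
            lo, hi = min(lo, hi), max(lo, hi)
            m = (geometry.s >= lo) & (geometry.s <= hi)
            if m.sum() >= 2:
                pieces.append(LineString(geometry.centerline[m]).buffer(half_w, quad_segs=8))
        if not pieces:
            continue
        seg_floor = unary_union(pieces)
        if seg_floor.area > 0:
            per_bin[b] = seg_floor.intersection(shadow).area / seg_floor.area
    if np.ptp(per_bin) > 0 and np.ptp(mids) > 0:
        corr = float(np.corrcoef(mids, per_bin)[0, 1])
    else:
        corr = 0.0
    return OcclusionResult(float(frac), float(1.0 - frac), mids, per_bin, corr)
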