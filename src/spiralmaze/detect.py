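"""Particle detection by pack-wise temporal background subtraction.

The stack is processed in packs (default 60 frames): a still background is
estimated per pack as the per-pixel temporal median (insects move, so the
median is free of them), each frame is subtracted from the background in
floating point (back-lit insects are darker than the floor, so the
difference is positive where an insect sits), the difference is thresholded,
and 8-connected components within an area range become detection records
carrying four shape descriptors: area, circularity, solidity, aspect ratio.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "estimate_background",
    "detect_frame",
    "analyze_sequence",
    "light_profile_along_path",
    "LightProfile",
]

DETECTION_COLUMNS = ["frame", "x", "y", "area",
                     "circularity", "solidity", "aspect_ratio"]


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the detection stage.

    threshold is in gray levels on the background-minus-frame difference;
    the paper's workflow sets it by eye, so it is a config value here (an
    Otsu-based automatic choice can be enabled with threshold="otsu").
    """

    threshold: float | str = 30.0
    area_min: float = 3.0  # px^2
    area_max: float = 400.0
    pack_size: int = 60
    projection: str = "median"  # or "mean"


def _as_stack(frames) -> np.ndarray:
    stack = np.asarray(frames)
    if stack.ndim != 3:
        raise ValueError("expected a (n, H, W) stack")
    if stack.dtype == np.uint16:
        stack = (stack / 257.0).astype(np.float32)  # rescale 16-bit to 8-bit range
    return stack


def estimate_background(frames, projection: str = "median") -> np.ndarray:
    """Temporal Z-projection of a stack: the still scene behind moving particles.

    Per-pixel median by default (robust to particles that visit a pixel in a
    minority of frames); per-pixel mean available via ``projection="mean"``.
    """
    stack = _as_stack(frames)
    if len(stack) < 2:
        raise ValueError("need at least 2 frames to estimate a background")
    if projection == "median":
        n = len(stack)
        if stack.dtype.kind in "ui":
            # partition-based median avoids a float copy of the whole stack
            k = [(n - 1) // 2, n // 2]
            part = np.partition(stack, k, axis=0)
            return 0.5 * (part[k[0]].astype(np.float64)
                          + part[k[1]].astype(np.float64))
        return np.median(stack, axis=0)
    if projection == "mean":
        return stack.mean(axis=0, dtype=np.float64)
    raise ValueError(f"unknown projection {projection!r}")


def _otsu_threshold(diff: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.clip(diff, 0, None)))


def _hull_area(pixels_x, pixels_y) -> float:
    """Convex hull area of a pixel set, hull taken over pixel-square corners
    (monotone chain + shoelace; pure python is fastest at blob size)."""
    corners = set()
    for x, y in zip(pixels_x, pixels_y):
        corners.add((x - 0.5, y - 0.5))
        corners.add((x - 0.5, y + 0.5))
        corners.add((x + 0.5, y - 0.5))
        corners.add((x + 0.5, y + 0.5))
    pts = sorted(corners)
    if len(pts) < 3:
        return 0.0

    def half(points):
        out = []
        for p in points:
            while len(out) >= 2:
                (ax, ay), (bx, by) = out[-2], out[-1]
                if (bx - ax) * (p[1] - ay) - (by - ay) * (p[0] - ax) <= 0:
                    out.pop()
                else:
                    break
            out.append(p)
        return out

    hull = half(pts)[:-1] + half(pts[::-1])[:-1]
    area2 = 0.0
    for (ax, ay), (bx, by) in zip(hull, hull[1:] + hull[:1]):
        area2 += ax * by - bx * ay
    return abs(area2) / 2.0


def detect_frame(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float | str = 30.0,
    area_range: Sequence[float] = (3.0, 400.0),
    frame_index: int = 0,
) -> pd.DataFrame:
    """Detect dark particles in one frame against a background.

    The floating-point difference ``background - frame`` is thresholded
    (pixels >= threshold), 8-connected components outside ``area_range`` are
    discarded, and each surviving component yields one record with centroid,
    area (px^2), circularity (4*pi*A/P^2, clipped to [0, 1]), solidity
    (A / convex hull A, hull taken over the pixel-square corners) and aspect
    ratio (moment-ellipse major/minor, >= 1).  The perimeter uses the
    boundary-crack convention: the count of exposed pixel edges scaled by
    pi/4 (the Cauchy-Crofton correction), which is exact in expectation for
    isotropic smooth boundaries.
    """
    frame = np.asarray(frame, dtype=np.float32)
    background = np.asarray(background, dtype=np.float32)
    if frame.shape != background.shape:
        raise ValueError("frame and background dimensions differ")
    diff = background - frame
    if threshold == "otsu":
        threshold = _otsu_threshold(diff)
    binary = diff >= float(threshold)
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return pd.DataFrame(columns=DETECTION_COLUMNS)

    ys, xs = np.nonzero(lab)
    l = lab[ys, xs]
    area = np.bincount(l, minlength=n + 1)[1:].astype(float)

    # first and central second moments per region
    sx = np.bincount(l, xs, n + 1)[1:]
    sy = np.bincount(l, ys, n + 1)[1:]
    cx, cy = sx / area, sy / area
    sxx = np.bincount(l, xs.astype(float) ** 2, n + 1)[1:]
    syy = np.bincount(l, ys.astype(float) ** 2, n + 1)[1:]
    sxy = np.bincount(l, xs.astype(float) * ys, n + 1)[1:]
    # +1/12: moment of a unit pixel square about its center
    mxx = sxx / area - cx ** 2 + 1.0 / 12.0
    myy = syy / area - cy ** 2 + 1.0 / 12.0
    mxy = sxy / area - cx * cy
    root = np.sqrt(((mxx - myy) / 2.0) ** 2 + mxy ** 2)
    lam1 = (mxx + myy) / 2.0 + root
    lam2 = np.clip((mxx + myy) / 2.0 - root, 0.0, None)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    aspect = np.where(minor > 1e-9, major / np.maximum(minor, 1e-9), np.inf)
    aspect = np.maximum(aspect, 1.0)

    # exposed 4-neighbor edges per region (crack count)
    crack = np.zeros(n + 1)
    padded = np.pad(lab, 1)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr:padded.shape[0] - 1 + dr,
                    1 + dc:padded.shape[1] - 1 + dc]
        edge = (core > 0) & (nb != core)
        crack += np.bincount(core[edge], minlength=n + 1)
    perim = (np.pi / 4.0) * crack[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.clip(4.0 * np.pi * area / perim ** 2, 0.0, 1.0)
    circ = np.where(perim > 0, circ, 1.0)

    lo, hi = area_range
    keep = np.nonzero((area >= lo) & (area <= hi))[0]

    # solidity only for surviving regions (convex hull of pixel corners)
    order = np.argsort(l, kind="stable")
    xo, yo = xs[order], ys[order]
    starts = np.searchsorted(l[order], np.arange(1, n + 2))
    solidity = np.ones(n)
    xo_l, yo_l = xo.tolist(), yo.tolist()
    for k in keep:
        a0, b0 = int(starts[k]), int(starts[k + 1])
        ha = _hull_area(xo_l[a0:b0], yo_l[a0:b0])
        solidity[k] = min(area[k] / ha, 1.0) if ha > 0 else 1.0

    return pd.DataFrame({
        "frame": frame_index,
        "x": cx[keep], "y": cy[keep], "area": area[keep],
        "circularity": circ[keep], "solidity": solidity[keep],
        "aspect_ratio": aspect[keep],
    })


def _iter_packs(frames, pack_size: int):
    """Yield (start_index, stack) per pack; accepts an array stack, a sequence
    of 2-D arrays, a list of file paths, or a directory of TIFFs."""
    if isinstance(frames, (str, os.PathLike)):
        names = sorted(f for f in os.listdir(frames)
                       if f.lower().endswith((".tif", ".tiff")))
        frames = [os.path.join(frames, n) for n in names]
    if isinstance(frames, np.ndarray):
        n = len(frames)
        for start in range(0, n, pack_size):
            yield start, frames[start:start + pack_size]
        return
    frames = list(frames)
    n = len(frames)

    def _load(item, index):
        if isinstance(item, (str, os.PathLike)):
            try:
                return tifffile.imread(item)
            except Exception as exc:  # propagate with frame index
                raise IOError(f"failed to read frame {index}: {item}") from exc
        return np.asarray(item)

    for start in range(0, n, pack_size):
        stack = np.stack([_load(frames[i], i)
                          for i in range(start, min(start + pack_size, n))])
        yield start, stack


def analyze_sequence(frames, params: DetectionParams = DetectionParams()) -> pd.DataFrame:
    """Run pack-wise detection over a whole image sequence.

    The background is re-estimated for every pack of ``params.pack_size``
    frames (non-overlapping windows); every frame is detected against its
    pack's background.  A final pack of fewer than 2 frames is merged into
    the previous one.  Output is one table of detection records in frame
    order; the run is deterministic.
    """
    if params.pack_size < 2:
        raise ValueError("pack_size must be >= 2")
    tables = []
    pending = None  # (start, stack) kept back in case the tail pack is short
    for start, stack in _iter_packs(frames, params.pack_size):
        if pending is not None:
            if len(stack) < 2:
                stack = np.concatenate([pending[1], stack])
                start = pending[0]
            else:
                tables.append(_detect_pack(*pending, params))
            pending = (start, stack)
        else:
            pending = (start, stack)
    if pending is not None:
        tables.append(_detect_pack(*pending, params))
    if not tables:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    return pd.concat(tables, ignore_index=True)


def _detect_pack(start, stack, params: DetectionParams) -> pd.DataFrame:
    stack = _as_stack(stack)
    bg = estimate_background(stack, projection=params.projection)
    out = []
    for j, frame in enumerate(stack):
        out.append(detect_frame(frame, bg, params.threshold,
                                (params.area_min, params.area_max),
                                frame_index=start + j))
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# lighting profile


@dataclass(frozen=True)
class LightProfile:
    s_mm: np.ndarray
    lux: np.ndarray
    mean_lux: float
    max_relative_deviation: float


def light_profile_along_path(
    image: np.ndarray,
    skeleton,
    lux_per_gray: Sequence[float] = (1.0, 0.0),
    step_px: int = 4,
) -> LightProfile:
    """Sample the pixel value along the path skeleton and convert to lux.

    ``lux_per_gray`` is the (gain, offset) of the linear scaling between
    pixel value and light intensity.  Returns the profile with its mean and
    the maximum relative deviation from the mean.
    """
    gain, offset = lux_per_gray
    if gain <= 0:
        raise ValueError("calibration gain must be positive")
    pts = skeleton.points[::step_px]
    s = skeleton.s_mm[::step_px]
    vals = ndimage.map_coordinates(np.asarray(image, dtype=float),
                                   [pts[:, 1], pts[:, 0]], order=1)
    lux = gain * vals + offset
    mean = float(lux.mean())
    dev = float(np.max(np.abs(lux - mean)) / mean) if mean != 0 else 0.0
    return LightProfile(s, lux, mean, dev)
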