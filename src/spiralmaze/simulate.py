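"""Synthetic dispersal and back-lit image rendering with ground truth.

Motion is simulated directly in the signed arc-length coordinate s (the
corridor is quasi-1-D at 1 cm width) as a per-phase Gaussian random walk with
reflecting tips, then embedded to 2-D via the maze centerline with a small
uniform lateral jitter.  Frames emulate the experimental optics: a bright,
mildly heterogeneous backlight seen through the corridor floor, dark walls,
and dark elliptical blobs (~0.5 mm insects, aspect ratio ~2.5) at the true
positions.  Every stage downstream of the camera is therefore testable
against exact ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .geometry import MazeGeometry, mm_to_px, render_tunnel_mask

__all__ = [
    "DispersalModel",
    "RenderConfig",
    "simulate_linear_dispersal",
    "render_sequence",
    "default_illumination",
    "write_frames",
]


@dataclass(frozen=True)
class DispersalModel:
    """Per-phase diffusive dispersal of a group released at s = 0.

    phases: ordered (duration_min, diffusion_mm2_per_min) pairs; all
    individuals switch phase synchronously (a documented simplification:
    the experiments give no individual-level switching model).
    """

    phases: tuple = ((360.0, 2.0),)
    n_individuals: int = 200
    boundary: str = "reflecting"
    seed: int = 0

    def __post_init__(self):
        if not self.phases:
            raise ValueError("at least one phase required")
        for dur, d in self.phases:
            if dur <= 0:
                raise ValueError("phase durations must be positive")
            if d < 0:
                raise ValueError("diffusion coefficients must be >= 0")
        if self.boundary != "reflecting":
            raise ValueError("only reflecting boundaries are supported")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.phases))

    def diffusion_at(self, t: float) -> float:
        """Diffusion coefficient (mm^2/min) in force during minute t."""
        acc = 0.0
        for dur, d in self.phases:
            acc += dur
            if t < acc:
                return float(d)
        return float(self.phases[-1][1])


def _reflect(s: np.ndarray, half_length: float) -> np.ndarray:
    """Fold positions into [-half_length, half_length] (reflecting tips)."""
    period = 4.0 * half_length
    x = np.mod(s + half_length, period)
    x = np.where(x > 2.0 * half_length, period - x, x)
    return x - half_length


def simulate_linear_dispersal(
    model: DispersalModel,
    half_length: float,
    n_frames: int = 360,
    dt: float = 1.0,
) -> np.ndarray:
    """Simulate arc positions; returns an (n_frames + 1, n_individuals) array.

    Row k holds positions at time k*dt; row 0 is the release (all zeros).
    Steps are unbiased Gaussians with variance 2*D(phase)*dt, reflected at
    the tunnel tips +-half_length.  Reproducible under the model seed.
    """
    if half_length <= 0:
        raise ValueError("half_length must be positive")
    rng = np.random.default_rng(model.seed)
    n = model.n_individuals
    out = np.zeros((n_frames + 1, n))
    s = np.zeros(n)
    for k in range(1, n_frames + 1):
        d = model.diffusion_at((k - 1) * dt)
        if d > 0:
            s = s + rng.normal(0.0, np.sqrt(2.0 * d * dt), size=n)
            s = _reflect(s, half_length)
        out[k] = s
    return out


# --------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class RenderConfig:
    """Optical parameters of the synthetic back-lit scene (8-bit gray)."""

    resolution: float = 4.0  # px per mm
    insect_length: float = 0.5  # mm; blob major axis
    insect_aspect: float = 2.5  # major/minor axis ratio
    blob_contrast: float = 140.0  # gray levels removed at the blob center
    backlight_level: float = 200.0  # mean tunnel brightness
    wall_level: float = 45.0  # brightness of walls (opaque PMMA)
    gradient: float = 0.10  # long-range horizontal gradient, fraction of level
    vignette: float = 0.06  # radial fall-off, fraction of level
    wave_amplitude: float = 0.0  # optional extra sinusoidal ripple fraction
    noise_sd: float = 2.0  # additive Gaussian pixel noise
    lateral_jitter: float = 1.0 / 3.0  # fraction of path_width, uniform
    hidden_fraction: float = 0.01  # per-observation prob. of wall concealment


def default_illumination(shape: tuple, config: RenderConfig) -> np.ndarray:
    """Backlight field with a horizontal gradient plus vignette, mimicking a
    large LED panel that is slightly dimmer at the extremities."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    xn = x / max(w - 1, 1) - 0.5
    yn = y / max(h - 1, 1) - 0.5
    field = np.ones(shape, dtype=np.float64)
    field += config.gradient * xn  # brighter toward +x
    field -= config.vignette * (xn ** 2 + yn ** 2) * 4.0
    if config.wave_amplitude:
        field += config.wave_amplitude * np.sin(2 * np.pi * 3 * (xn + 0.1) )
    return config.backlight_level * field


def _stamp_blobs(frame, centers_px, angles, major_px, minor_px, depth):
    """Darken anti-aliased ellipses in-place."""
    h, w = frame.shape
    r = int(np.ceil(major_px / 2.0)) + 2
    for (cx, cy), ang in zip(centers_px, angles):
        x0, y0 = int(round(cx)), int(round(cy))
        xa, xb = max(x0 - r, 0), min(x0 + r + 1, w)
        ya, yb = max(y0 - r, 0), min(y0 + r + 1, h)
        if xa >= xb or ya >= yb:
            continue
        yy, xx = np.mgrid[ya:yb, xa:xb]
        dx, dy = xx - cx, yy - cy
        ca, sa = np.cos(ang), np.sin(ang)
        u = (dx * ca + dy * sa) / (major_px / 2.0)
        v = (-dx * sa + dy * ca) / (minor_px / 2.0)
        rho = np.sqrt(u * u + v * v)
        alpha = np.clip((1.15 - rho) / 0.3, 0.0, 1.0)
        frame[ya:yb, xa:xb] -= depth * alpha


def render_sequence(
    geometry: MazeGeometry,
    positions: np.ndarray,
    config: RenderConfig = RenderConfig(),
    illumination: np.ndarray | None = None,
    seed: int = 0,
    out_dir: str | None = None,
):
    """Render TIFF-style 8-bit frames for simulated arc positions.

    Parameters
    ----------
    geometry : MazeGeometry
    positions : (n_frames, n_individuals) signed arc positions in mm
        (e.g. the output of :func:`simulate_linear_dispersal`).
    config : RenderConfig
    illumination : optional 2-D field; defaults to
        :func:`default_illumination` (gradient + vignette).
    seed : controls jitter, blob orientation, concealment and pixel noise.
    out_dir : if given, frames are written there as zero-padded TIFFs and a
        list of file paths is returned in place of the stack.

    Returns
    -------
    frames : (n_frames, H, W) uint8 array, or list of paths if out_dir given
    truth : DataFrame (frame, id, s_mm, x_px, y_px, visible)
    """
    res = config.resolution
    major_px = config.insect_length * res
    if major_px < 2.0:
        raise ValueError(
            f"insect length {config.insect_length} mm at {res} px/mm gives a "
            f"{major_px:.1f} px blob; need >= 2 px"
        )
    minor_px = max(major_px / config.insect_aspect, 1.2)
    rng = np.random.default_rng(seed)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n_frames, n_ind = positions.shape

    mask = render_tunnel_mask(geometry, res)
    h, w = mask.shape
    if illumination is None:
        illumination = default_illumination((h, w), config)
    background = np.where(mask, illumination,
                          illumination * (config.wall_level / config.backlight_level)
                          ).astype(np.float32)

    frames = [] if out_dir is None else None
    paths = []
    truth_rows = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    jit_half = config.lateral_jitter * geometry.path_width

    for k in range(n_frames):
        s = positions[k]
        jitter = rng.uniform(-jit_half, jit_half, size=n_ind)
        pos_mm = geometry.point_at(s) + geometry.normal_at(s) * jitter[:, None]
        pos_px = mm_to_px(pos_mm, res, geometry.plate_width, geometry.plate_height)
        angles = rng.uniform(0.0, np.pi, size=n_ind)
        visible = rng.random(n_ind) >= config.hidden_fraction
        frame = background.copy()
        _stamp_blobs(frame, pos_px[visible], angles[visible],
                     major_px, minor_px, config.blob_contrast)
        if config.noise_sd > 0:
            noise = rng.standard_normal(frame.shape, dtype=np.float32)
            noise *= config.noise_sd
            frame += noise
        np.clip(frame, 0, 255, out=frame)
        img = frame.astype(np.uint8)
        truth_rows.append((np.full(n_ind, k), np.arange(n_ind), s.copy(),
                           pos_px[:, 0], pos_px[:, 1], visible))
        if out_dir is None:
            frames.append(img)
        else:
            p = os.path.join(out_dir, f"frame_{k:04d}.tif")
            tifffile.imwrite(p, img)
            paths.append(p)

    cols = ["frame", "id", "s_mm", "x_px", "y_px", "visible"]
    truth = pd.DataFrame({c: np.concatenate([r[j] for r in truth_rows])
                          for j, c in enumerate(cols)})
    truth["frame"] = truth["frame"].astype(int)
    truth["id"] = truth["id"].astype(int)
    truth["visible"] = truth["visible"].astype(bool)
    if out_dir is None:
        return np.stack(frames), truth
    return paths, truth


def write_frames(frames: np.ndarray, out_dir: str) -> list:
    """Write a frame stack as zero-padded single-page TIFFs."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for k, img in enumerate(frames):
        p = os.path.join(out_dir, f"frame_{k:04d}.tif")
        tifffile.imwrite(p, np.asarray(img, dtype=np.uint8))
        paths.append(p)
    return paths
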