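"""Post-detection cleaning: redundancy, size, edge-distance and shape filters.

Each filter is a pure predicate on a detection row (plus, for redundancy, the
whole table), so output membership does not depend on application order; the
removal counts are reported for the fixed order redundancy -> area -> edge ->
circularity, attributing each removed row to the first filter that rejects it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterConfig", "apply_filters"]

FILTER_ORDER = ("redundancy", "area", "edge", "circularity")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the four cleaning filters (toolkit defaults, not
    published values; the experimental protocol leaves them unspecified).

    redundancy: a position (rounded to ``redundancy_tol_px``) occupied in
    more than ``redundancy_max_frame_frac`` of all frames is a static
    artifact (dust, glued host eggs): an insect pauses, but rarely for half
    the experiment.  area bounds are px^2 on the detected particle.  The edge
    filter bounds the perpendicular offset from the skeleton as a fraction of
    the path half-width, removing wall-shadow artifacts.  circularity_min
    keeps compact insect-like shapes.
    """

    redundancy_tol_px: float = 2.0
    redundancy_max_frame_frac: float = 0.5
    area_min: float = 15.0
    area_max: float = 120.0
    edge_max_frac: float = 0.9
    circularity_min: float = 0.4

    def __post_init__(self):
        if self.redundancy_tol_px <= 0 or self.area_min <= 0:
            raise ValueError("filter bounds must be positive")
        if not (0 < self.redundancy_max_frame_frac <= 1):
            raise ValueError("redundancy_max_frame_frac must be in (0, 1]")
        if not (0 < self.edge_max_frac <= 1):
            raise ValueError("edge_max_frac must be in (0, 1]")


def apply_filters(
    detections: pd.DataFrame,
    config: FilterConfig,
    path_width_mm: float = 10.0,
    n_frames: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the four cleaning filters to a projected detection table.

    ``detections`` must carry x, y, frame, area, circularity and the
    projection columns s_mm / perp_mm.  Returns the surviving subset (all
    columns preserved, plus one boolean pass column per filter) and a dict of
    per-filter removal counts for the fixed application order.
    """
    df = detections.copy()
    if n_frames is None:
        n_frames = int(df["frame"].nunique()) if len(df) else 0

    # redundancy: same rounded spot recurring in most frames
    if len(df):
        tol = config.redundancy_tol_px
        key = (np.floor(df["x"] / tol).astype(int).astype(str) + "_"
               + np.floor(df["y"] / tol).astype(int).astype(str))
        frames_per_spot = df.groupby(key)["frame"].transform("nunique")
        limit = config.redundancy_max_frame_frac * max(n_frames, 1)
        df["pass_redundancy"] = (frames_per_spot <= limit).to_numpy()
    else:
        df["pass_redundancy"] = np.array([], dtype=bool)

    df["pass_area"] = (df["area"] >= config.area_min) & (df["area"] <= config.area_max)
    df["pass_edge"] = df["perp_mm"] <= config.edge_max_frac * path_width_mm / 2.0
    df["pass_circularity"] = df["circularity"] >= config.circularity_min

    removed = {}
    alive = pd.Series(True, index=df.index)
    for name in FILTER_ORDER:
        fail = alive & ~df[f"pass_{name}"]
        removed[name] = int(fail.sum())
        alive &= df[f"pass_{name}"]
    removed["kept"] = int(alive.sum())
    return df[alive].copy(), removed
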