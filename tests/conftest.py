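"""Shared fixtures: compact maze geometries and rendered sequences.

All fixtures are generated programmatically; session scope keeps the more
expensive ones (skeletons, rendered stacks) to a single build.
"""

import numpy as np
import pytest

from spiralmaze import DispersalModel, RenderConfig, render_sequence, simulate_linear_dispersal
from spiralmaze.geometry import MazeGeometry
from spiralmaze.linearize import skeleton_for_geometry
from spiralmaze.pipeline import compact_maze


@pytest.fixture(scope="session")
def maze():
    """Compact double spiral (~0.62 m tunnel in a 150 x 112 mm plate)."""
    return compact_maze()


@pytest.fixture(scope="session")
def maze_skeleton(maze):
    return skeleton_for_geometry(maze, resolution=4.0)


@pytest.fixture(scope="session")
def straight_tunnel():
    """A 100 x 10 mm straight corridor expressed as a MazeGeometry."""
    n = 501
    x = np.linspace(-50.0, 50.0, n)
    centerline = np.stack([x, np.zeros(n)], axis=-1)
    return MazeGeometry(
        plate_width=120.0, plate_height=40.0, path_width=10.0,
        wall_width=2.0, wall_height=5.0, n_turns_per_arm=0.0,
        handedness="levogyrous", centerline=centerline, s=x.copy(),
    )


@pytest.fixture(scope="session")
def sparse_clean_run(maze):
    """A short, sparse, low-noise rendered experiment with ground truth:
    insects are well separated after the first frames, so detection and
    projection can be validated against truth without crowding effects."""
    model = DispersalModel(phases=((120.0, 30.0),), n_individuals=12, seed=11)
    positions = simulate_linear_dispersal(model, min(maze.arm_lengths),
                                          n_frames=120)
    config = RenderConfig(noise_sd=1.0, hidden_fraction=0.0)
    frames, truth = render_sequence(maze, positions, config, seed=12)
    return frames, truth, config
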