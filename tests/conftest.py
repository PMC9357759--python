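"""Shared fixtures: layouts, graphs, and small random problem generators."""

from __future__ import annotations

import numpy as np
import pytest

from msstgcn import skeleton_graph as sg

DEFAULT_LAYOUT_NAMES = ("synthetic20", "coco18", "ntu25")


@pytest.fixture(scope="session", params=DEFAULT_LAYOUT_NAMES)
def any_layout(request) -> sg.SkeletonLayout:
    """Each built-in layout in turn."""
    return sg.build_layout(request.param)


@pytest.fixture(scope="session")
def layout20() -> sg.SkeletonLayout:
    return sg.build_layout("synthetic20")


@pytest.fixture(scope="session")
def graph20(layout20) -> sg.GraphTensors:
    return sg.build_graph(layout20)


def random_tree_layout(rng: np.random.Generator, v: int) -> sg.SkeletonLayout:
    """A random connected tree on ``v`` joints with a random template pose."""
    edges = tuple((int(rng.integers(0, i)), i) for i in range(1, v))
    pose = rng.standard_normal((v, 3))
    return sg.SkeletonLayout(
        name=f"random{v}",
        joint_names=tuple(f"j{i}" for i in range(v)),
        edges=edges,
        template_pose=pose,
        center_joint=int(rng.integers(0, v)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
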