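"""Skeleton layouts and spatial graph construction.

A skeleton is an undirected graph whose vertices are body joints and whose
edges follow anatomical bone connections.  Every graph-convolution layer in
the network consumes three fixed matrices derived from a layout:

* the symmetrically normalized adjacency ``G = Λ^{-1/2} (A + I) Λ^{-1/2}``,
  where ``Λ`` is the degree matrix of ``A + I`` (self-loops included), and
* its split into three spatial-partition subsets, obtained by comparing each
  neighbor's distance to the skeleton's center of gravity (the mean of all
  template joint coordinates) with the root joint's distance: equal distance
  (label 0, "stationary"), closer (label 1, "centripetal"), farther
  (label 2, "centrifugal").

The partition is computed once per layout from its canonical template pose,
so the subset matrices — and the learnable edge-importance masks that share
their shape — are fixed for the lifetime of a model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SkeletonLayout",
    "GraphTensors",
    "LayoutError",
    "build_layout",
    "available_layouts",
    "adjacency_from_layout",
    "normalize_adjacency",
    "partition_spatial",
    "build_graph",
    "load_layout_file",
    "save_layout_file",
]

LAYOUT_FORMAT_VERSION = 1

#: Distance ties to the center of gravity are decided within this tolerance.
DISTANCE_TIE_ATOL = 1e-6


class LayoutError(ValueError):
    """Raised when a skeleton layout fails validation."""


@dataclass(frozen=True)
class SkeletonLayout:
    """Static definition of a skeleton: joints, bones and a canonical pose.

    Parameters
    ----------
    name
        Identifier of the layout.
    joint_names
        One name per joint; its length fixes the joint count ``V``.
    edges
        Unordered joint-index pairs (the intra-frame bone edge set).
    template_pose
        ``(V, 3)`` canonical joint coordinates in normalized body lengths,
        used to compute the center-of-gravity partition.
    center_joint
        Index of the joint used as the origin for coordinate centering.
    """

    name: str
    joint_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    template_pose: np.ndarray
    center_joint: int = 0

    def __post_init__(self) -> None:
        v = len(self.joint_names)
        if v < 1:
            raise LayoutError("layout needs at least one joint")
        pose = np.asarray(self.template_pose, dtype=np.float64)
        if pose.shape != (v, 3):
            raise LayoutError(
                f"template_pose shape {pose.shape} does not match ({v}, 3)"
            )
        object.__setattr__(self, "template_pose", pose)
        seen: set[tuple[int, int]] = set()
        canonical = []
        for i, j in self.edges:
            if not (0 <= i < v and 0 <= j < v):
                raise LayoutError(f"edge ({i}, {j}) out of range for {v} joints")
            if i == j:
                raise LayoutError(f"self-loop edge ({i}, {j}) not allowed")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise LayoutError(f"duplicate edge ({i}, {j})")
            seen.add(key)
            canonical.append(key)
        object.__setattr__(self, "edges", tuple(canonical))
        if not 0 <= self.center_joint < v:
            raise LayoutError(f"center_joint {self.center_joint} out of range")
        # distinct template coordinates guarantee a well-defined partition
        diff = pose[:, None, :] - pose[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if np.any(dist < 1e-12):
            raise LayoutError("template_pose places two joints at the same point")
        if v > 1:
            self._check_connected(v)

    def _check_connected(self, v: int) -> None:
        adj: list[list[int]] = [[] for _ in range(v)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != v:
            raise LayoutError(
                f"edge list is disconnected: reached {len(seen)} of {v} joints"
            )

    @property
    def num_joints(self) -> int:
        return len(self.joint_names)

    def centroid(self) -> np.ndarray:
        """Center of gravity: mean coordinate of all template joints."""
        return self.template_pose.mean(axis=0)


@dataclass(frozen=True)
class GraphTensors:
    """Adjacency-derived matrices consumed by the graph-convolution layers."""

    adjacency: np.ndarray  # (V, V) binary, symmetric, zero diagonal
    degree: np.ndarray  # (V,) diagonal of Λ = D(A) + I
    normalized: np.ndarray  # (V, V) Λ^{-1/2} (A + I) Λ^{-1/2}
    subsets: np.ndarray  # (3, V, V) partition of `normalized`
    subset_labels: np.ndarray = field(default=None)  # (V, V) int in {-1,0,1,2}

    @property
    def num_joints(self) -> int:
        return self.adjacency.shape[0]


# --------------------------------------------------------------------------
# Built-in layouts
# --------------------------------------------------------------------------

def _synthetic20() -> SkeletonLayout:
    """Default 20-joint layout: a humanoid tree in a T-pose.

    Coordinates are in units of roughly one torso length, x to the
    subject's left, y up, z forward; the pelvis is the root and the
    coordinate-centering reference.
    """
    names = (
        "pelvis", "spine", "chest", "neck", "head", "head_top",
        "l_shoulder", "l_elbow", "l_wrist",
        "r_shoulder", "r_elbow", "r_wrist",
        "l_hip", "l_knee", "l_ankle", "l_foot",
        "r_hip", "r_knee", "r_ankle", "r_foot",
    )
    pose = np.array([
        [0.00, 0.00, 0.0],   # pelvis
        [0.00, 0.30, 0.0],   # spine
        [0.00, 0.60, 0.0],   # chest
        [0.00, 0.80, 0.0],   # neck
        [0.00, 1.00, 0.0],   # head
        [0.00, 1.15, 0.0],   # head_top
        [0.25, 0.75, 0.0],   # l_shoulder
        [0.55, 0.75, 0.0],   # l_elbow
        [0.85, 0.75, 0.0],   # l_wrist
        [-0.25, 0.75, 0.0],  # r_shoulder
        [-0.55, 0.75, 0.0],  # r_elbow
        [-0.85, 0.75, 0.0],  # r_wrist
        [0.15, -0.10, 0.0],  # l_hip
        [0.18, -0.55, 0.0],  # l_knee
        [0.20, -1.00, 0.0],  # l_ankle
        [0.30, -1.10, 0.0],  # l_foot
        [-0.15, -0.10, 0.0],  # r_hip
        [-0.18, -0.55, 0.0],  # r_knee
        [-0.20, -1.00, 0.0],  # r_ankle
        [-0.30, -1.10, 0.0],  # r_foot
    ])
    edges = (
        (0, 1), (1, 2), (2, 3), (3, 4), (4, 5),
        (2, 6), (6, 7), (7, 8),
        (2, 9), (9, 10), (10, 11),
        (0, 12), (12, 13), (13, 14), (14, 15),
        (0, 16), (16, 17), (17, 18), (18, 19),
    )
    return SkeletonLayout("synthetic20", names, edges, pose, center_joint=0)


def _coco18() -> SkeletonLayout:
    """18-keypoint layout matching the OpenPose COCO output order."""
    names = (
        "nose", "neck",
        "r_shoulder", "r_elbow", "r_wrist",
        "l_shoulder", "l_elbow", "l_wrist",
        "r_hip", "r_knee", "r_ankle",
        "l_hip", "l_knee", "l_ankle",
        "r_eye", "l_eye", "r_ear", "l_ear",
    )
    pose = np.array([
        [0.00, 0.95, 0.0],   # nose
        [0.00, 0.75, 0.0],   # neck
        [-0.20, 0.75, 0.0],  # r_shoulder
        [-0.25, 0.45, 0.0],  # r_elbow
        [-0.27, 0.18, 0.0],  # r_wrist
        [0.20, 0.75, 0.0],   # l_shoulder
        [0.25, 0.45, 0.0],   # l_elbow
        [0.27, 0.18, 0.0],   # l_wrist
        [-0.13, 0.00, 0.0],  # r_hip
        [-0.15, -0.50, 0.0],  # r_knee
        [-0.16, -1.00, 0.0],  # r_ankle
        [0.13, 0.00, 0.0],   # l_hip
        [0.15, -0.50, 0.0],  # l_knee
        [0.16, -1.00, 0.0],  # l_ankle
        [-0.06, 1.02, 0.0],  # r_eye
        [0.06, 1.02, 0.0],   # l_eye
        [-0.12, 0.97, 0.0],  # r_ear
        [0.12, 0.97, 0.0],   # l_ear
    ])
    edges = (
        (0, 1), (1, 2), (2, 3), (3, 4), (1, 5), (5, 6), (6, 7),
        (1, 8), (8, 9), (9, 10), (1, 11), (11, 12), (12, 13),
        (0, 14), (14, 16), (0, 15), (15, 17),
    )
    return SkeletonLayout("coco18", names, edges, pose, center_joint=1)


def _ntu25() -> SkeletonLayout:
    """25-joint layout following the Kinect-v2 skeleton used by NTU RGB+D."""
    names = (
        "spine_base", "spine_mid", "neck", "head",
        "l_shoulder", "l_elbow", "l_wrist", "l_hand",
        "r_shoulder", "r_elbow", "r_wrist", "r_hand",
        "l_hip", "l_knee", "l_ankle", "l_foot",
        "r_hip", "r_knee", "r_ankle", "r_foot",
        "spine_shoulder",
        "l_hand_tip", "l_thumb", "r_hand_tip", "r_thumb",
    )
    pose = np.array([
        [0.00, 0.00, 0.0],   # spine_base
        [0.00, 0.25, 0.0],   # spine_mid
        [0.00, 0.55, 0.0],   # neck
        [0.00, 0.70, 0.0],   # head
        [0.20, 0.50, 0.0],   # l_shoulder
        [0.45, 0.50, 0.0],   # l_elbow
        [0.70, 0.50, 0.0],   # l_wrist
        [0.80, 0.50, 0.0],   # l_hand
        [-0.20, 0.50, 0.0],  # r_shoulder
        [-0.45, 0.50, 0.0],  # r_elbow
        [-0.70, 0.50, 0.0],  # r_wrist
        [-0.80, 0.50, 0.0],  # r_hand
        [0.12, -0.05, 0.0],  # l_hip
        [0.15, -0.50, 0.0],  # l_knee
        [0.17, -0.95, 0.0],  # l_ankle
        [0.25, -1.05, 0.0],  # l_foot
        [-0.12, -0.05, 0.0],  # r_hip
        [-0.15, -0.50, 0.0],  # r_knee
        [-0.17, -0.95, 0.0],  # r_ankle
        [-0.25, -1.05, 0.0],  # r_foot
        [0.00, 0.45, 0.0],   # spine_shoulder
        [0.90, 0.50, 0.0],   # l_hand_tip
        [0.82, 0.44, 0.0],   # l_thumb
        [-0.90, 0.50, 0.0],  # r_hand_tip
        [-0.82, 0.44, 0.0],  # r_thumb
    ])
    edges = (
        (0, 1), (1, 20), (2, 20), (2, 3),
        (4, 20), (4, 5), (5, 6), (6, 7),
        (8, 20), (8, 9), (9, 10), (10, 11),
        (0, 12), (12, 13), (13, 14), (14, 15),
        (0, 16), (16, 17), (17, 18), (18, 19),
        (7, 21), (7, 22), (11, 23), (11, 24),
    )
    return SkeletonLayout("ntu25", names, edges, pose, center_joint=20)


_BUILTIN = {"synthetic20": _synthetic20, "coco18": _coco18, "ntu25": _ntu25}


def available_layouts() -> tuple[str, ...]:
    return tuple(sorted(_BUILTIN))


def build_layout(name: str | Path) -> SkeletonLayout:
    """Return a built-in layout by name, or load one from a layout file.

    ``name`` may be one of :func:`available_layouts` or a path to a
    YAML/JSON layout file (see :func:`load_layout_file`).
    """
    key = str(name)
    if key in _BUILTIN:
        return _BUILTIN[key]()
    path = Path(name)
    if path.suffix.lower() in {".yaml", ".yml", ".json"} or path.exists():
        return load_layout_file(path)
    raise LayoutError(
        f"unknown layout {key!r}; expected one of {available_layouts()} "
        "or a path to a layout file"
    )


def load_layout_file(path: str | Path) -> SkeletonLayout:
    """Load a layout from a versioned YAML or JSON file.

    Schema (format_version 1)::

        format_version: 1
        name: my_layout
        joints: [name0, name1, ...]
        edges: [[0, 1], [1, 2], ...]
        template_pose: [[x, y, z], ...]   # one triple per joint
        center_joint: 0
    """
    path = Path(path)
    if not path.exists():
        raise LayoutError(f"layout file {path} does not exist")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            import yaml

            doc = yaml.safe_load(text)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise LayoutError(f"cannot parse layout file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise LayoutError(f"layout file {path} must contain a mapping")
    version = doc.get("format_version", 1)
    if version != LAYOUT_FORMAT_VERSION:
        raise LayoutError(
            f"layout file {path} has format_version {version}; "
            f"this package reads version {LAYOUT_FORMAT_VERSION}"
        )
    missing = {"name", "joints", "edges", "template_pose"} - set(doc)
    if missing:
        raise LayoutError(f"layout file {path} missing keys {sorted(missing)}")
    return SkeletonLayout(
        name=str(doc["name"]),
        joint_names=tuple(str(j) for j in doc["joints"]),
        edges=tuple((int(i), int(j)) for i, j in doc["edges"]),
        template_pose=np.asarray(doc["template_pose"], dtype=np.float64),
        center_joint=int(doc.get("center_joint", 0)),
    )


def save_layout_file(layout: SkeletonLayout, path: str | Path) -> None:
    """Write a layout to a YAML or JSON layout file (schema version 1)."""
    doc = {
        "format_version": LAYOUT_FORMAT_VERSION,
        "name": layout.name,
        "joints": list(layout.joint_names),
        "edges": [list(e) for e in layout.edges],
        "template_pose": layout.template_pose.tolist(),
        "center_joint": layout.center_joint,
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# --------------------------------------------------------------------------
# Graph algebra
# --------------------------------------------------------------------------

def adjacency_from_layout(layout: SkeletonLayout) -> np.ndarray:
    """Binary symmetric adjacency with zero diagonal, one 1-pair per bone."""
    v = layout.num_joints
    adj = np.zeros((v, v), dtype=np.float64)
    for i, j in layout.edges:
        adj[i, j] = 1.0
        adj[j, i] = 1.0
    return adj


def normalize_adjacency(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric normalization ``Λ^{-1/2} (A + I) Λ^{-1/2}``.

    ``Λ`` is diagonal with ``Λ_xx = Σ_y A_xy + 1`` — the degree of joint
    ``x`` counting its self-loop — so every row of the result is a weighted
    average over the joint's closed neighborhood and all eigenvalues lie in
    ``[-1, 1]``.

    Returns
    -------
    normalized, degree
        The ``(V, V)`` normalized matrix and the length-``V`` diagonal of Λ.
    """
    adj = np.asarray(adjacency, dtype=np.float64)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if not np.all(np.isin(adj, (0.0, 1.0))):
        raise ValueError("adjacency entries must be 0 or 1")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero")
    degree = adj.sum(axis=1) + 1.0
    inv_sqrt = 1.0 / np.sqrt(degree)
    with_loops = adj + np.eye(adj.shape[0])
    normalized = inv_sqrt[:, None] * with_loops * inv_sqrt[None, :]
    return normalized, degree


def partition_spatial(
    layout: SkeletonLayout,
    normalized: np.ndarray,
    *,
    atol: float = DISTANCE_TIE_ATOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the normalized adjacency into the three distance subsets.

    For root joint ``x`` and neighbor ``y`` (any pair with a nonzero entry
    in ``A + I``, including ``y = x``), the label compares template
    distances to the center of gravity ``r = ‖pose − centroid‖₂``:

    ========  ==================  =======================
    label     condition           motion interpretation
    ========  ==================  =======================
    0         ``r_y = r_x``       stationary
    1         ``r_y < r_x``       centripetal
    2         ``r_y > r_x``       centrifugal
    ========  ==================  =======================

    Equality is decided within ``atol``.  Entries that are not neighbors
    get label −1 and belong to no subset.

    Returns
    -------
    subsets, subset_labels
        ``(3, V, V)`` matrices with disjoint support summing elementwise to
        ``normalized``, and the ``(V, V)`` integer label map.
    """
    v = layout.num_joints
    normalized = np.asarray(normalized, dtype=np.float64)
    if normalized.shape != (v, v):
        raise ValueError(
            f"normalized matrix shape {normalized.shape} does not match "
            f"layout with {v} joints"
        )
    radii = np.linalg.norm(layout.template_pose - layout.centroid(), axis=1)
    support = adjacency_from_layout(layout) + np.eye(v) > 0
    diff = radii[None, :] - radii[:, None]  # r_y - r_x at (x, y)
    labels = np.full((v, v), -1, dtype=np.int64)
    labels[support & (np.abs(diff) <= atol)] = 0
    labels[support & (diff < -atol)] = 1
    labels[support & (diff > atol)] = 2
    subsets = np.zeros((3, v, v), dtype=np.float64)
    for z in range(3):
        subsets[z] = np.where(labels == z, normalized, 0.0)
    return subsets, labels


def build_graph(layout: SkeletonLayout) -> GraphTensors:
    """Convenience: adjacency → normalization → partition in one call."""
    adjacency = adjacency_from_layout(layout)
    normalized, degree = normalize_adjacency(adjacency)
    subsets, labels = partition_spatial(layout, normalized)
    return GraphTensors(
        adjacency=adjacency,
        degree=degree,
        normalized=normalized,
        subsets=subsets,
        subset_labels=labels,
    )
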