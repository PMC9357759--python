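"""Turn raw multi-person keypoint detections into fixed-shape model inputs.

The model consumes dense arrays shaped ``(C, T, V, M)``: channels, frames,
joints, person slots.  Raw pose-estimator output is ragged — a varying
number of candidate skeletons per frame — so the pipeline here selects the
top-``k`` candidates by mean joint confidence, resamples every sequence to a
common frame count (25 by default), centers coordinates on a reference
joint, and optionally applies a random 3-D rotation of up to ±18° per axis
as training augmentation.

Channel semantics are carried by each sequence's ``channels`` tuple:
2-D pose data uses ``("x", "y", "conf")``; 3-D data uses
``("x", "y", "z")`` optionally followed by ``"conf"``.  The confidence
channel is never rotated or translated, and person/joint slots that are
exactly zero (missing detections) stay exactly zero through every step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .skeleton_graph import SkeletonLayout

__all__ = [
    "SkeletonSequence",
    "DEFAULT_FRAMES",
    "DEFAULT_PERSONS",
    "DEFAULT_MAX_ROTATION_DEGREES",
    "select_top_persons",
    "resample_frames",
    "random_rotation_augment",
    "normalize_coordinates",
    "rotation_matrix",
]

#: Common frame count every sequence is resampled to.
DEFAULT_FRAMES = 25
#: Number of person slots kept per frame (highest mean confidence first).
DEFAULT_PERSONS = 2
#: Per-axis bound of the random rotation augmentation, degrees.
DEFAULT_MAX_ROTATION_DEGREES = 18.0

CHANNELS_2D = ("x", "y", "conf")
CHANNELS_3D = ("x", "y", "z")

_SPATIAL = ("x", "y", "z")


@dataclass
class SkeletonSequence:
    """One pose sample: a dense ``(C, T, V, M)`` array plus metadata.

    Attributes
    ----------
    data
        ``(channels, frames, joints, persons)`` float array.  Missing
        detections are exact zeros across all channels.
    channels
        Name of each channel; spatial channels are ``"x"``, ``"y"``,
        ``"z"`` and the optional confidence channel is ``"conf"``.
    label
        Class index, or ``None`` for unlabelled data.
    meta
        Free-form source identifier.
    """

    data: np.ndarray
    channels: tuple[str, ...] = CHANNELS_2D
    label: int | None = None
    meta: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim != 4:
            raise ValueError(f"data must be (C, T, V, M), got shape {data.shape}")
        if data.shape[0] != len(self.channels):
            raise ValueError(
                f"{data.shape[0]} data channels but {len(self.channels)} names"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("sequence contains NaN or Inf")
        self.data = data
        self.channels = tuple(self.channels)

    @property
    def num_channels(self) -> int:
        return self.data.shape[0]

    @property
    def num_frames(self) -> int:
        return self.data.shape[1]

    @property
    def num_joints(self) -> int:
        return self.data.shape[2]

    @property
    def num_persons(self) -> int:
        return self.data.shape[3]

    def spatial_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c in _SPATIAL]

    def confidence_index(self) -> int | None:
        return self.channels.index("conf") if "conf" in self.channels else None

    def copy(self) -> "SkeletonSequence":
        return replace(self, data=self.data.copy())


def _zero_mask(data: np.ndarray) -> np.ndarray:
    """(T, V, M) boolean mask of entries that are zero across all channels."""
    return np.all(data == 0.0, axis=0)


def select_top_persons(
    detections: list[list[np.ndarray]],
    k: int = DEFAULT_PERSONS,
    *,
    num_joints: int,
    channels: tuple[str, ...] = CHANNELS_2D,
    label: int | None = None,
    meta: str = "",
) -> SkeletonSequence:
    """Keep the ``k`` candidates with highest mean joint confidence per frame.

    Parameters
    ----------
    detections
        Per-frame list of candidate skeletons; each candidate is a
        ``(V, C)`` array whose last channel is the per-joint confidence.
        Frames may hold any number of candidates, including none.
    k
        Person slots in the output (default 2).  Slots are filled in
        descending order of mean confidence; ties keep the original
        detection order; missing candidates are zero-filled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if "conf" not in channels:
        raise ValueError("person selection requires a confidence channel")
    conf_idx = channels.index("conf")
    c = len(channels)
    t = len(detections)
    data = np.zeros((c, max(t, 1), num_joints, k), dtype=np.float32)
    for f, frame in enumerate(detections):
        if not frame:
            continue
        cands = [np.asarray(p, dtype=np.float32) for p in frame]
        for p in cands:
            if p.shape != (num_joints, c):
                raise ValueError(
                    f"candidate shape {p.shape} does not match "
                    f"({num_joints}, {c})"
                )
        means = np.array([p[:, conf_idx].mean() for p in cands])
        # stable sort on negated confidence: ties keep original order
        order = np.argsort(-means, kind="stable")[:k]
        for slot, idx in enumerate(order):
            data[:, f, :, slot] = cands[idx].T
    return SkeletonSequence(data, channels=channels, label=label, meta=meta)


def resample_frames(seq: SkeletonSequence, target: int = DEFAULT_FRAMES) -> SkeletonSequence:
    """Bring a sequence to exactly ``target`` frames.

    Longer sequences are uniformly subsampled at indices
    ``floor(arange(target) * T / target)`` — strictly increasing, so frame
    order is preserved and no frame repeats.  Shorter sequences are
    loop-padded by repeating from the first frame.  Equal length is the
    identity.
    """
    if target < 1:
        raise ValueError("target frame count must be >= 1")
    t = seq.num_frames
    if t < 1:
        raise ValueError("cannot resample an empty sequence")
    if t == target:
        return seq.copy()
    if t > target:
        idx = np.floor(np.arange(target) * (t / target)).astype(np.int64)
    else:
        idx = np.arange(target) % t
    return replace(seq, data=seq.data[:, idx].copy())


def rotation_matrix(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Composed rotation ``R = Rz @ Ry @ Rx`` for angles in radians."""
    cx, sx = np.cos(theta_x), np.sin(theta_x)
    cy, sy = np.cos(theta_y), np.sin(theta_y)
    cz, sz = np.cos(theta_z), np.sin(theta_z)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def random_rotation_augment(
    seq: SkeletonSequence,
    max_degrees: float = DEFAULT_MAX_ROTATION_DEGREES,
    rng: int | np.random.Generator = 0,
) -> SkeletonSequence:
    """Rotate all joints by one random angle triple drawn per sequence.

    Angles ``(θx, θy, θz)`` are drawn uniformly from
    ``[-max_degrees, +max_degrees]³`` and applied as ``Rz·Ry·Rx`` about the
    sequence's mean joint position, so the skeleton spins in place rather
    than orbiting the origin.  With 2-D data (channels x, y) only the
    in-plane rotation about the z axis is applied (``θx = θy = 0``).  The
    confidence channel and exactly-zero (missing) entries are untouched.
    """
    if max_degrees < 0:
        raise ValueError("max_degrees must be >= 0")
    spatial = seq.spatial_indices()
    if len(spatial) < 2:
        raise ValueError(
            "rotation augmentation needs at least 2 spatial channels; "
            "confidence is non-spatial — set the sequence's channel names"
        )
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bound = np.deg2rad(max_degrees)
    angles = gen.uniform(-bound, bound, size=3)
    two_d = len(spatial) == 2
    if two_d:
        angles[0] = angles[1] = 0.0
    rot = rotation_matrix(*angles)
    data = seq.data.copy()
    zero = _zero_mask(seq.data)  # (T, V, M)
    coords = np.zeros((3,) + seq.data.shape[1:], dtype=np.float64)
    for axis, ch in enumerate(spatial):
        coords[axis] = seq.data[ch]
    present = ~zero
    if present.any():
        center = coords[:, present].mean(axis=1)
        shifted = coords - center[:, None, None, None]
        rotated = np.einsum("ab,btvm->atvm", rot, shifted) + center[:, None, None, None]
        for axis, ch in enumerate(spatial):
            data[ch] = rotated[axis].astype(np.float32)
            data[ch][zero] = 0.0
    return replace(seq, data=data)


def normalize_coordinates(seq: SkeletonSequence, layout: SkeletonLayout) -> SkeletonSequence:
    """Translate spatial channels so the reference joint sits at the origin.

    The reference is the layout's ``center_joint`` of person 0 in frame 0.
    Zero-filled (missing) entries remain exactly zero, and the confidence
    channel is untouched.  Composing any constant translation with this
    step is a no-op, which makes downstream predictions invariant to the
    absolute position of the subject.
    """
    spatial = seq.spatial_indices()
    if not spatial:
        return seq.copy()
    data = seq.data.copy()
    zero = _zero_mask(seq.data)
    # reference missing (all-zero) degenerates to the identity translation,
    # which also makes an already-centered sequence a fixed point
    ref = seq.data[spatial, 0, layout.center_joint, 0]
    for axis, ch in enumerate(spatial):
        data[ch] = seq.data[ch] - ref[axis]
        data[ch][zero] = 0.0
    return replace(seq, data=data)
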