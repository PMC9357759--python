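"""Reading pose data, the dataset archive format, and run configuration.

Three external formats are handled here:

* **OpenPose keypoint JSON** — one file per frame, each holding a
  ``people`` list whose entries carry a flat ``(x, y, confidence)`` triple
  per keypoint (field ``pose_keypoints_2d`` in the common dialect; a 3-D
  field name can be supplied instead).  Frames are ordered by natural
  filename sort; empty ``people`` lists are legal and yield empty frames.

* **Dataset archive** — an HDF5 file holding a homogeneous batch
  ``data (N, C, T, V, M)``, integer ``labels``, the channel names and the
  layout name, under a versioned schema.  Round-trips are bitwise exact,
  and neither frames nor persons are ever reordered by the reader.

* **Run configuration** — a YAML document with ``model``, ``train`` and
  ``fusion`` sections mirroring :class:`~msstgcn.classifier_network.ModelConfig`,
  :class:`TrainConfig` and :class:`~msstgcn.classifier_network.FusionConfig`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .classifier_network import FusionConfig, ModelConfig
from .preprocessing import SkeletonSequence
from .skeleton_graph import SkeletonLayout

__all__ = [
    "DatasetFormatError",
    "TrainConfig",
    "RunConfig",
    "read_openpose_json",
    "write_dataset",
    "read_dataset",
    "stack_sequences",
]

DATASET_FORMAT_VERSION = 1


class DatasetFormatError(ValueError):
    """Raised when a dataset archive violates the documented schema."""


# --------------------------------------------------------------------------
# OpenPose JSON
# --------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str) -> tuple:
    return tuple(int(p) if p.isdigit() else p for p in _NUM_RE.split(name))


def read_openpose_json(
    directory: str | Path,
    layout: SkeletonLayout,
    *,
    keypoint_field: str = "pose_keypoints_2d",
) -> list[list[np.ndarray]]:
    """Parse a directory of per-frame OpenPose JSON files.

    Returns per-frame lists of candidate skeletons, each a ``(V, 3)``
    array of (x, y, confidence) rows, in natural filename order — the
    shape :func:`msstgcn.preprocessing.select_top_persons` consumes.

    Raises
    ------
    ValueError
        Naming the offending file, on malformed JSON or on a keypoint
        count that does not match the layout.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValueError(f"{directory} is not a directory")
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() == ".json"),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise ValueError(f"no .json files found in {directory}")
    v = layout.num_joints
    frames: list[list[np.ndarray]] = []
    for path in files:
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON in {path}: {exc}") from exc
        people = doc.get("people", [])
        candidates: list[np.ndarray] = []
        for i, person in enumerate(people):
            flat = person.get(keypoint_field)
            if flat is None:
                raise ValueError(
                    f"{path}: person {i} has no field {keypoint_field!r}"
                )
            arr = np.asarray(flat, dtype=np.float32)
            if arr.size % 3 != 0:
                raise ValueError(
                    f"{path}: person {i} keypoint array length {arr.size} "
                    "is not a multiple of 3"
                )
            arr = arr.reshape(-1, 3)
            if arr.shape[0] != v:
                raise ValueError(
                    f"{path}: person {i} has {arr.shape[0]} keypoints, "
                    f"layout {layout.name!r} expects {v}"
                )
            candidates.append(arr)
        frames.append(candidates)
    return frames


# --------------------------------------------------------------------------
# Dataset archive
# --------------------------------------------------------------------------

def stack_sequences(
    sequences: list[SkeletonSequence],
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Stack homogeneous sequences into ``(X, y, channels)``.

    Every sequence must share shape and channel names (run the
    preprocessing pipeline first); unlabelled sequences get label −1.
    """
    if not sequences:
        raise ValueError("no sequences to stack")
    shape = sequences[0].data.shape
    channels = sequences[0].channels
    for s in sequences:
        if s.data.shape != shape or s.channels != channels:
            raise ValueError(
                "sequences are not homogeneous: "
                f"{s.data.shape}/{s.channels} vs {shape}/{channels}"
            )
    x = np.stack([s.data for s in sequences])
    y = np.array([-1 if s.label is None else s.label for s in sequences], dtype=np.int64)
    return x, y, channels


def write_dataset(
    path: str | Path,
    sequences: list[SkeletonSequence] | np.ndarray,
    labels: np.ndarray | None = None,
    *,
    layout_name: str,
    channels: tuple[str, ...] | None = None,
) -> None:
    """Write a dataset archive (HDF5, schema version 1).

    ``sequences`` may be a list of homogeneous :class:`SkeletonSequence`
    (labels taken from the sequences) or a pre-stacked ``(N, C, T, V, M)``
    array together with ``labels`` and ``channels``.
    """
    if isinstance(sequences, np.ndarray):
        if labels is None or channels is None:
            raise ValueError("array input needs explicit labels and channels")
        x, y = sequences, np.asarray(labels, dtype=np.int64)
    else:
        x, y, channels = stack_sequences(sequences)
        if labels is not None:
            y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 5:
        raise ValueError(f"data must be (N, C, T, V, M), got shape {x.shape}")
    if len(y) != x.shape[0]:
        raise ValueError(f"{x.shape[0]} sequences but {len(y)} labels")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = DATASET_FORMAT_VERSION
        f.attrs["layout_name"] = layout_name
        f.attrs["channels"] = list(channels)
        f.create_dataset("data", data=x, compression="gzip", compression_opts=4)
        f.create_dataset("labels", data=y)


def read_dataset(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], str]:
    """Read a dataset archive; returns ``(data, labels, channels, layout_name)``.

    Frame and person order is preserved exactly as written.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None:
            raise DatasetFormatError(f"{path} has no format_version attribute")
        if int(version) != DATASET_FORMAT_VERSION:
            raise DatasetFormatError(
                f"{path} has format_version {version}; this package reads "
                f"version {DATASET_FORMAT_VERSION}"
            )
        if "data" not in f:
            raise DatasetFormatError(f"{path} is missing the 'data' dataset")
        if "labels" not in f:
            raise DatasetFormatError(f"{path} is missing the 'labels' table")
        x = f["data"][...]
        y = f["labels"][...]
        channels = tuple(str(c) for c in f.attrs["channels"])
        layout_name = str(f.attrs["layout_name"])
    if x.shape[0] != y.shape[0]:
        raise DatasetFormatError(
            f"{path}: {x.shape[0]} sequences but {y.shape[0]} labels"
        )
    return x, y, channels, layout_name


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the reference training recipe: SGD with momentum 0.9,
    learning rate 0.001, batch size 10, 150 epochs, per-epoch random
    rotation augmentation of ±18°.
    """

    learning_rate: float = 0.001
    batch_size: int = 10
    epochs: int = 150
    momentum: float = 0.9
    optimizer: str = "sgd"  # "sgd" or "adam"
    warmup_epochs: int = 0  # linear learning-rate ramp over the first epochs
    seed: int = 0
    augment: bool = True
    max_rotation_degrees: float = 18.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Everything one training run needs: model, optimization, fusion."""

    model: ModelConfig
    train: TrainConfig = TrainConfig()
    fusion: FusionConfig = FusionConfig()

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "train": asdict(self.train),
            "fusion": asdict(self.fusion),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        return cls(
            model=ModelConfig.from_dict(doc["model"]),
            train=TrainConfig(**doc.get("train", {})),
            fusion=FusionConfig(**doc.get("fusion", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict) or "model" not in doc:
            raise ValueError(f"config file {path} must contain a 'model' section")
        return cls.from_dict(doc)
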