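"""The full multiscale spatio-temporal graph-convolution classifier.

Architecture, front to back:

1. input batch normalization over the flattened person × joint × channel
   axis, which standardizes raw coordinates per joint and channel;
2. persons folded into the batch axis;
3. a stack of :class:`~msstgcn.network_layers.STGCNBlock` (10 by default);
4. global average pooling over frames and joints, mean over persons;
5. dropout, a linear map to class scores, softmax.

Two independently trained networks — typically a joint-coordinate stream
and a bone-vector stream — can be combined at the probability level with
:func:`fuse_scores`, the convex combination ``α·u_g + (1−α)·u_h``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import skeleton_graph
from .nn_core import BatchNorm, Dropout, Linear, Module, softmax
from .network_layers import STGCNBlock

__all__ = [
    "ModelConfig",
    "FusionConfig",
    "MSSTGCN",
    "build_model",
    "fuse_scores",
    "count_parameters",
    "bone_stream",
    "save_checkpoint",
    "load_checkpoint",
]

#: Per-block output channels of the default 10-layer backbone.  Widths are
#: kept deliberately small: the architecture's design point is a lightweight
#: model (well under one million trainable parameters) that trains in
#: minutes on a single CPU core at desk scale.
DEFAULT_CHANNEL_PLAN = (8, 8, 8, 8, 16, 16, 16, 16, 16, 16)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``gamma`` is the base temporal kernel extent; the multiscale block
    pairs it with ``2·gamma``.  ``channel_plan`` must have one (even)
    entry per block.
    """

    num_classes: int
    num_layers: int = 10
    channel_plan: tuple[int, ...] = DEFAULT_CHANNEL_PLAN
    gamma: int = 8
    strides: tuple[int, ...] | None = None
    dropout: float = 0.25
    layout_name: str = "synthetic20"
    in_channels: int = 3
    num_persons: int = 2
    multiscale: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_plan", tuple(self.channel_plan))
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.channel_plan) != self.num_layers:
            raise ValueError(
                f"channel_plan has {len(self.channel_plan)} entries for "
                f"{self.num_layers} layers"
            )
        if self.multiscale and any(c % 2 for c in self.channel_plan):
            raise ValueError("all channels must be even (the filter split halves them)")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.num_persons < 1:
            raise ValueError("num_persons must be >= 1")
        strides = self.strides if self.strides is not None else (1,) * self.num_layers
        strides = tuple(int(s) for s in strides)
        if len(strides) != self.num_layers:
            raise ValueError("strides must have one entry per layer")
        object.__setattr__(self, "strides", strides)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        doc = dict(doc)
        for key in ("channel_plan", "strides"):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass(frozen=True)
class FusionConfig:
    """Weight of the first stream in the two-stream score fusion."""

    alpha: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


class MSSTGCN(Module):
    """Multiscale spatio-temporal graph-convolution classifier.

    Consumes batches shaped ``(N, C, T, V, M)`` — samples, channels,
    frames, joints, persons — and emits per-class probabilities.
    """

    def __init__(self, config: ModelConfig, *, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        layout = skeleton_graph.build_layout(config.layout_name)
        graph = skeleton_graph.build_graph(layout)
        self.layout = layout
        self.num_joints = layout.num_joints
        rng = np.random.default_rng(seed)
        self._dtype = dtype
        self.input_bn = self.add_module(
            "input_bn",
            BatchNorm(config.in_channels * layout.num_joints * config.num_persons,
                      dtype=dtype),
        )
        self.blocks: list[STGCNBlock] = []
        c_prev = config.in_channels
        for i, (c_out, stride) in enumerate(zip(config.channel_plan, config.strides)):
            block = STGCNBlock(
                c_prev,
                c_out,
                graph.subsets,
                config.gamma,
                stride=stride,
                multiscale=config.multiscale,
                residual=i > 0,
                rng=rng,
                dtype=dtype,
            )
            self.add_module(f"block{i}", block)
            self.blocks.append(block)
            c_prev = c_out
        self.dropout = self.add_module("dropout", Dropout(config.dropout, rng=rng))
        self.fc = self.add_module("fc", Linear(c_prev, config.num_classes, rng=rng, dtype=dtype))

    # -- plumbing ----------------------------------------------------------

    def _validate(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=self._dtype)
        if batch.ndim != 5:
            raise ValueError(f"batch must be (N, C, T, V, M), got {batch.shape}")
        if batch.shape[1] != self.config.in_channels:
            raise ValueError(
                f"batch has {batch.shape[1]} channels, model expects "
                f"{self.config.in_channels}"
            )
        if batch.shape[3] != self.num_joints:
            raise ValueError(
                f"batch has {batch.shape[3]} joints, layout "
                f"{self.layout.name} has {self.num_joints}"
            )
        if batch.shape[4] != self.config.num_persons:
            raise ValueError(
                f"batch has {batch.shape[4]} person slots, model expects "
                f"{self.config.num_persons}"
            )
        if not np.all(np.isfinite(batch)):
            raise ValueError("batch contains NaN or Inf")
        return batch

    # -- forward / backward ------------------------------------------------

    def forward_logits(self, batch: np.ndarray) -> np.ndarray:
        """Raw class scores, shape ``(N, num_classes)``."""
        batch = self._validate(batch)
        n, c, t, v, m = batch.shape
        # (N, C, T, V, M) -> (N, T, M, V, C) -> flatten features for BN
        x = batch.transpose(0, 2, 4, 3, 1)
        x = self.input_bn(x.reshape(n, t, 1, m * v * c)).reshape(n, t, m, v, c)
        # fold persons into the batch axis, channel-last for the blocks
        x = np.ascontiguousarray(x.transpose(0, 2, 1, 3, 4)).reshape(n * m, t, v, c)
        for block in self.blocks:
            x = block(x)
        self._pool_shape = x.shape  # (N*M, T', V, C_last)
        pooled = x.mean(axis=(1, 2))  # global average over frames and joints
        self._nm = (n, m)
        per_person = pooled.reshape(n, m, -1)
        merged = per_person.mean(axis=1)  # mean over person slots
        merged = self.dropout(merged)
        return self.fc(merged)

    def backward(self, grad_logits: np.ndarray) -> None:
        """Accumulate parameter gradients from a loss gradient on the logits."""
        n, m = self._nm
        g = self.fc.backward(grad_logits)
        g = self.dropout.backward(g)
        g = np.repeat(g[:, None, :] / m, m, axis=1).reshape(n * m, -1)
        nm, t, v, c = self._pool_shape
        g = (np.broadcast_to(g[:, None, None, :], self._pool_shape) / (t * v)).astype(
            g.dtype
        )
        for block in reversed(self.blocks):
            g = block.backward(g)
        # through the input batch-norm; the raw-input gradient is discarded
        nm2, t0, v0, c0 = g.shape
        g = g.reshape(n, m, t0, v0, c0).transpose(0, 2, 1, 3, 4)
        self.input_bn.backward(np.ascontiguousarray(g).reshape(n, t0, 1, m * v0 * c0))

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Class probabilities; rows sum to one."""
        return softmax(self.forward_logits(batch))

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(batch)


def build_model(config: ModelConfig, *, seed: int = 0) -> MSSTGCN:
    """Instantiate a model with reproducible parameter initialization."""
    return MSSTGCN(config, seed=seed)


def count_parameters(model: MSSTGCN) -> int:
    """Total number of trainable scalars in the model."""
    return int(sum(p.size for p in model.parameters()))


def fuse_scores(
    u_g: np.ndarray, u_h: np.ndarray, fusion: FusionConfig | float = FusionConfig()
) -> np.ndarray:
    """Linear weighted score fusion ``α·u_g + (1−α)·u_h``.

    Both inputs must be matrices of class-probability rows with matching
    shape; the output is again row-stochastic because the combination is
    convex.
    """
    if not isinstance(fusion, FusionConfig):
        fusion = FusionConfig(alpha=float(fusion))
    u_g = np.asarray(u_g, dtype=np.float64)
    u_h = np.asarray(u_h, dtype=np.float64)
    if u_g.shape != u_h.shape:
        raise ValueError(f"shape mismatch: {u_g.shape} vs {u_h.shape}")
    for name, u in (("u_g", u_g), ("u_h", u_h)):
        if np.any(u < -1e-9):
            raise ValueError(f"{name} has negative entries")
        if not np.allclose(u.sum(axis=-1), 1.0, atol=1e-4):
            raise ValueError(f"rows of {name} must sum to 1")
    return fusion.alpha * u_g + (1.0 - fusion.alpha) * u_h


def bone_stream(batch: np.ndarray, layout) -> np.ndarray:
    """Map a joint-coordinate batch to its bone-vector counterpart.

    Each bone (layout edge) contributes the coordinate difference
    child − parent, stored at the child joint's slot; the root joint (the
    layout's ``center_joint``) holds zeros.  Shapes are unchanged, so the
    bone stream trains on the identical architecture.  Parent/child
    orientation follows a traversal rooted at ``center_joint``.
    """
    batch = np.asarray(batch)
    v = layout.num_joints
    if batch.shape[3] != v:
        raise ValueError(f"batch has {batch.shape[3]} joints, layout has {v}")
    parent = np.full(v, -1, dtype=np.int64)
    adj: list[list[int]] = [[] for _ in range(v)]
    for i, j in layout.edges:
        adj[i].append(j)
        adj[j].append(i)
    root = layout.center_joint
    stack, seen = [root], {root}
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                parent[nb] = node
                stack.append(nb)
    out = np.zeros_like(batch)
    children = np.where(parent >= 0)[0]
    out[:, :, :, children] = batch[:, :, :, children] - batch[:, :, :, parent[children]]
    return out


# --------------------------------------------------------------------------
# Checkpoints: a single .npz holding the config and every named array
# --------------------------------------------------------------------------

def _batchnorms(module: Module, prefix: str = "") -> list[tuple[str, BatchNorm]]:
    out = []
    if isinstance(module, BatchNorm):
        out.append((prefix.rstrip("."), module))
    for name, sub in module._modules.items():
        out.extend(_batchnorms(sub, prefix + name + "."))
    return out


def save_checkpoint(model: MSSTGCN, path: str | Path) -> None:
    """Write config plus every parameter and BN running statistic to ``path``."""
    arrays: dict[str, np.ndarray] = {}
    for name, p in model.named_parameters():
        arrays["param/" + name] = p.value
    for name, bn in _batchnorms(model):
        arrays["running_mean/" + name] = bn.running_mean
        arrays["running_var/" + name] = bn.running_var
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": model.config.to_dict(),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> MSSTGCN:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"checkpoint {path} has format_version {meta.get('format_version')}; "
                f"this package reads version {CHECKPOINT_FORMAT_VERSION}"
            )
        model = MSSTGCN(ModelConfig.from_dict(meta["config"]))
        params = dict(model.named_parameters())
        for key in archive.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                if name not in params:
                    raise ValueError(f"checkpoint parameter {name!r} not in model")
                params[name].value = archive[key].copy()
        bns = dict(_batchnorms(model))
        for key in archive.files:
            if key.startswith("running_mean/"):
                bns[key[len("running_mean/"):]].running_mean = archive[key].copy()
            elif key.startswith("running_var/"):
                bns[key[len("running_var/"):]].running_var = archive[key].copy()
    model.eval()
    return model
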