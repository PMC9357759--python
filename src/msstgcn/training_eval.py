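"""Training, top-k evaluation, and the comparison harnesses.

The training loop minimizes cross-entropy with SGD-with-momentum or Adam,
with optional per-epoch random-rotation augmentation.  All randomness — batch
order, augmentation angles, parameter initialization — derives from
explicit integer seeds, so two runs with the same seeds produce identical
loss curves.

Two experiment harnesses mirror the method's comparison protocol on
synthetic data: :func:`scale_ablation` trains single-scale and multiscale
temporal-convolution arms under identical seeds and reports the signed
accuracy difference, and :func:`two_stream_alpha_sweep` trains a
joint-coordinate stream and a bone-vector stream and sweeps the fusion
weight α over the grid {0.2, …, 0.8}.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import skeleton_graph
from .classifier_network import (
    FusionConfig,
    MSSTGCN,
    ModelConfig,
    bone_stream,
    build_model,
    fuse_scores,
    save_checkpoint,
)
from .data_io import TrainConfig, stack_sequences
from .nn_core import Adam, SGD, cross_entropy_with_grad, softmax
from .preprocessing import (
    CHANNELS_2D,
    DEFAULT_FRAMES,
    SkeletonSequence,
    normalize_coordinates,
    random_rotation_augment,
    resample_frames,
)
from .synthetic_actions import SyntheticSpec, generate_dataset, stratified_split

__all__ = [
    "EpochRecord",
    "TrainHistory",
    "QUICK_PROFILE",
    "TABLE1_PROFILE",
    "ALPHA_GRID",
    "prepare_sequences",
    "train",
    "evaluate",
    "quick_benchmark",
    "scale_ablation",
    "two_stream_alpha_sweep",
]

#: Desk-scale profile: Adam with linear warmup, 25 epochs; minutes on one CPU.
QUICK_PROFILE = TrainConfig(
    learning_rate=0.005, batch_size=10, epochs=25, optimizer="adam",
    warmup_epochs=12, augment=False, seed=0
)
#: Reference recipe: lr 0.001, batch 10, 150 epochs, ±18° augmentation.
TABLE1_PROFILE = TrainConfig()

#: Fusion-weight grid swept by the two-stream harness.
ALPHA_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_accuracy: float | None
    learning_rate: float
    wall_time_s: float


@dataclass
class TrainHistory:
    """Per-epoch metrics plus the path of the best checkpoint, if saved."""

    records: list[EpochRecord] = field(default_factory=list)
    checkpoint_path: str | None = None

    @property
    def train_losses(self) -> list[float]:
        return [r.train_loss for r in self.records]

    @property
    def val_accuracies(self) -> list[float | None]:
        return [r.val_accuracy for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(
                ["epoch", "train_loss", "train_accuracy", "val_accuracy",
                 "learning_rate", "wall_time_s"]
            )
            for r in self.records:
                writer.writerow(
                    [r.epoch, f"{r.train_loss:.6f}", f"{r.train_accuracy:.4f}",
                     "" if r.val_accuracy is None else f"{r.val_accuracy:.4f}",
                     r.learning_rate, f"{r.wall_time_s:.2f}"]
                )


def prepare_sequences(
    sequences: list[SkeletonSequence],
    layout: skeleton_graph.SkeletonLayout,
    frames: int = DEFAULT_FRAMES,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Standard input pipeline: resample, center, stack.

    Returns ``(X, y, channels)`` with ``X`` shaped ``(N, C, frames, V, M)``.
    """
    processed = [
        normalize_coordinates(resample_frames(s, frames), layout) for s in sequences
    ]
    return stack_sequences(processed)


def _augment_batch(
    x: np.ndarray,
    channels: tuple[str, ...],
    max_degrees: float,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        seq = SkeletonSequence(x[i], channels=channels)
        out[i] = random_rotation_augment(seq, max_degrees, rng).data
    return out


def _snapshot(model: MSSTGCN) -> dict:
    from .classifier_network import _batchnorms

    return {
        "params": {n: p.value.copy() for n, p in model.named_parameters()},
        "bn": {
            n: (bn.running_mean.copy(), bn.running_var.copy())
            for n, bn in _batchnorms(model)
        },
    }


def _restore(model: MSSTGCN, snap: dict) -> None:
    from .classifier_network import _batchnorms

    for n, p in model.named_parameters():
        p.value[...] = snap["params"][n]
    for n, bn in _batchnorms(model):
        bn.running_mean, bn.running_var = (
            snap["bn"][n][0].copy(),
            snap["bn"][n][1].copy(),
        )


def _dataset_loss(model, x, y, batch_size):
    """Deterministic loss/accuracy over a dataset with batch statistics.

    Uses the same normalization the optimizer sees (per-batch statistics)
    but with dropout disabled and without touching the running averages,
    so the recorded curve is noise-free and reproducible."""
    from .classifier_network import _batchnorms

    was_training = model.training
    bns = [bn for _, bn in _batchnorms(model)]
    saved_stats = [(bn.running_mean.copy(), bn.running_var.copy()) for bn in bns]
    saved_p = model.dropout.p
    model.dropout.p = 0.0
    model.train()
    n = x.shape[0]
    # fixed mixed-class order: batch statistics then resemble training batches
    order = np.random.default_rng(0).permutation(n)
    batch_size = max(batch_size, min(n, 40))
    total, correct = 0.0, 0
    try:
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            logits = model.forward_logits(x[idx])
            yb = y[idx]
            loss, _ = cross_entropy_with_grad(logits, yb)
            total += loss * len(yb)
            correct += int((logits.argmax(axis=1) == yb).sum())
    finally:
        model.dropout.p = saved_p
        for bn, (mean, var) in zip(bns, saved_stats):
            bn.running_mean, bn.running_var = mean, var
        if not was_training:
            model.eval()
    return float(total / n), correct / n


def train(
    model: MSSTGCN,
    train_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = QUICK_PROFILE,
    *,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
    channels: tuple[str, ...] = CHANNELS_2D,
    out_dir: str | Path | None = None,
) -> tuple[MSSTGCN, TrainHistory]:
    """Optimize ``model`` on ``(X, y)`` and return it with its history.

    When ``val_data`` is given, validation accuracy is tracked per epoch
    and the best-validation parameters are restored at the end (and saved
    to ``out_dir`` if provided, together with the metrics CSV).
    """
    x, y = train_data
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() >= model.config.num_classes:
        raise ValueError(
            f"labels span [{y.min()}, {y.max()}] but the model has "
            f"{model.config.num_classes} classes"
        )
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    if config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate)
    else:
        opt = SGD(params, lr=config.learning_rate, momentum=config.momentum)
    history = TrainHistory()
    best_val, best_snap = -np.inf, None
    start = time.perf_counter()
    for epoch in range(config.epochs):
        model.train()
        if config.warmup_epochs > 0:
            opt.lr = config.learning_rate * min(1.0, (epoch + 1) / config.warmup_epochs)
        order = rng.permutation(n)
        xe, ye = x[order], y[order]
        if config.augment:
            xe = _augment_batch(xe, channels, config.max_rotation_degrees, rng)
        for lo in range(0, n, config.batch_size):
            xb = xe[lo : lo + config.batch_size]
            yb = ye[lo : lo + config.batch_size]
            logits = model.forward_logits(xb)
            loss, grad = cross_entropy_with_grad(logits, yb)
            model.zero_grad()
            model.backward(grad)
            opt.step()
        # deterministic end-of-epoch metrics: eval mode, no dropout noise
        train_loss, train_acc = _dataset_loss(model, x, y, config.batch_size)
        val_acc = None
        if val_data is not None:
            val_acc = evaluate(model, *val_data, ks=(1,))[1]
            if val_acc > best_val:
                best_val, best_snap = val_acc, _snapshot(model)
        history.records.append(
            EpochRecord(
                epoch=epoch,
                train_loss=train_loss,
                train_accuracy=train_acc,
                val_accuracy=val_acc,
                learning_rate=opt.lr,
                wall_time_s=time.perf_counter() - start,
            )
        )
    if best_snap is not None:
        _restore(model, best_snap)
    model.eval()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "model.ckpt.npz"
        save_checkpoint(model, ckpt)
        history.checkpoint_path = str(ckpt)
        history.to_csv(out_dir / "history.csv")
    return model, history


def evaluate(
    model: MSSTGCN,
    x: np.ndarray,
    y: np.ndarray,
    ks: tuple[int, ...] = (1,),
    *,
    batch_size: int = 32,
) -> dict[int, float]:
    """Top-k accuracy for each ``k``: fraction of samples whose true label
    is among the k highest-probability classes.  ``k >= num_classes``
    gives exactly 1.0."""
    if any(k < 1 for k in ks):
        raise ValueError("every k must be >= 1")
    probs = predict_probabilities(model, x, batch_size=batch_size)
    y = np.asarray(y)
    order = np.argsort(-probs, axis=1)  # descending probability
    ranks = np.argmax(order == y[:, None], axis=1)  # rank of the true class
    return {int(k): float((ranks < k).mean()) for k in ks}


def predict_probabilities(
    model: MSSTGCN, x: np.ndarray, *, batch_size: int = 32
) -> np.ndarray:
    """Class-probability matrix in eval mode, batched to bound memory."""
    was_training = model.training
    model.eval()
    chunks = [
        softmax(model.forward_logits(x[lo : lo + batch_size]))
        for lo in range(0, x.shape[0], batch_size)
    ]
    if was_training:
        model.train()
    return np.concatenate(chunks, axis=0)


# --------------------------------------------------------------------------
# Desk-scale benchmark and comparison harnesses
# --------------------------------------------------------------------------

def _benchmark_data(
    *,
    num_classes: int,
    n_train: int,
    n_test: int,
    seed: int,
    spec: SyntheticSpec | None = None,
):
    spec = spec or SyntheticSpec(num_classes=num_classes)
    layout = skeleton_graph.build_layout(spec.layout_name)
    sequences, labels = generate_dataset(spec, n_train + n_test, rng_seed=seed)
    tr_s, tr_y, te_s, te_y = stratified_split(sequences, labels, n_test, rng_seed=seed)
    xtr, ytr, channels = prepare_sequences(tr_s, layout)
    xte, yte, _ = prepare_sequences(te_s, layout)
    return spec, layout, (xtr, tr_y), (xte, te_y), channels


def quick_benchmark(
    seed: int = 7,
    *,
    num_classes: int = 4,
    n_train: int = 50,
    n_test: int = 20,
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """End-to-end benchmark: synthetic data → default model → top-1 accuracy.

    Generates ``n_train``/``n_test`` sequences per class from the default
    4-class synthetic spec, trains the default model under the quick
    profile and returns the history plus final top-1 test accuracy.
    """
    spec, layout, (xtr, ytr), (xte, yte), channels = _benchmark_data(
        num_classes=num_classes, n_train=n_train, n_test=n_test, seed=seed
    )
    cfg = config or replace(QUICK_PROFILE, seed=seed)
    mcfg = model_config or ModelConfig(
        num_classes=num_classes, in_channels=len(channels), layout_name=spec.layout_name
    )
    model = build_model(mcfg, seed=seed)
    model, history = train(
        model, (xtr, ytr), cfg, val_data=(xte, yte), channels=channels, out_dir=out_dir
    )
    accuracy = evaluate(model, xte, yte, ks=(1,))
    return {
        "model": model,
        "history": history,
        "top1": accuracy[1],
        "test_data": (xte, yte),
        "train_data": (xtr, ytr),
        "channels": channels,
    }


def scale_ablation(
    seed: int = 7,
    *,
    num_classes: int = 4,
    n_train: int = 12,
    n_test: int = 8,
    epochs: int = 12,
    csv_path: str | Path | None = None,
) -> dict:
    """Single-scale vs multiscale temporal convolution under identical seeds.

    Both arms share the dataset, initialization seed and optimization
    settings; only the temporal-convolution mode differs.  Returns the two
    top-1 accuracies and their signed difference (multiscale − single),
    optionally writing a two-column CSV (algorithm, top-1 %).
    """
    spec, layout, train_set, test_set, channels = _benchmark_data(
        num_classes=num_classes, n_train=n_train, n_test=n_test, seed=seed
    )
    cfg = replace(QUICK_PROFILE, epochs=epochs, warmup_epochs=max(2, epochs // 3),
                  seed=seed)
    results = {}
    for name, multiscale in (("single_scale", False), ("multiscale", True)):
        mcfg = ModelConfig(
            num_classes=num_classes,
            in_channels=len(channels),
            layout_name=spec.layout_name,
            multiscale=multiscale,
        )
        model = build_model(mcfg, seed=seed)
        model, _ = train(model, train_set, cfg, channels=channels)
        results[name] = evaluate(model, *test_set, ks=(1,))[1]
    results["difference"] = results["multiscale"] - results["single_scale"]
    if csv_path is not None:
        with open(csv_path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["algorithm", "top1_percent"])
            writer.writerow(["single_scale", f"{100 * results['single_scale']:.2f}"])
            writer.writerow(["multiscale", f"{100 * results['multiscale']:.2f}"])
    return results


def two_stream_alpha_sweep(
    seed: int = 7,
    *,
    num_classes: int = 4,
    n_train: int = 12,
    n_test: int = 8,
    epochs: int = 12,
    alphas: tuple[float, ...] = ALPHA_GRID,
    model_config: ModelConfig | None = None,
    csv_path: str | Path | None = None,
) -> dict:
    """Train joint and bone streams, fuse scores over the α grid.

    The joint stream sees raw coordinates; the bone stream sees per-edge
    coordinate differences (child − parent) through the identical
    architecture.  Returns per-α fused top-1 accuracies and the argmax α.
    """
    spec, layout, (xtr, ytr), (xte, yte), channels = _benchmark_data(
        num_classes=num_classes, n_train=n_train, n_test=n_test, seed=seed
    )
    cfg = replace(QUICK_PROFILE, epochs=epochs, warmup_epochs=max(2, epochs // 3),
                  seed=seed)
    mcfg = model_config or ModelConfig(
        num_classes=num_classes, in_channels=len(channels), layout_name=spec.layout_name
    )
    probs = {}
    for name, tf in (("joint", lambda a: a), ("bone", lambda a: bone_stream(a, layout))):
        model = build_model(mcfg, seed=seed + (0 if name == "joint" else 1))
        model, _ = train(model, (tf(xtr), ytr), cfg, channels=channels)
        probs[name] = predict_probabilities(model, tf(xte))
    sweep = {}
    for alpha in alphas:
        fused = fuse_scores(probs["joint"], probs["bone"], FusionConfig(alpha=alpha))
        order = np.argsort(-fused, axis=1)
        sweep[alpha] = float((order[:, 0] == yte).mean())
    best_alpha = max(sweep, key=sweep.get)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["alpha", "top1_percent"])
            for alpha in alphas:
                writer.writerow([alpha, f"{100 * sweep[alpha]:.2f}"])
    return {"sweep": sweep, "best_alpha": best_alpha, "streams": probs, "labels": yte}
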