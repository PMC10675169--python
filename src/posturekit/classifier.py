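"""Multilabel frame classifier: a small residual/VGG-hybrid 2-D CNN.

The network maps a 2 x 21 x 50 encoded frame to eight independent label
scores in [0, 1]: a 3x3 convolution stem, a stack of residual stages (each a
VGG-style double-convolution block with identity skip, 2x downsampling
between stages), global average pooling and a dense 8-unit sigmoid head.
Training minimizes mean per-label binary cross-entropy on a stratified 90/10
split; posture exclusivity and the walking rule are enforced by
post-processing, not by the loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .annotation import AnnotationTrack
from .frame_encoding import FRAME_SHAPE, EncodedFrame, FrameDataset, SENSOR_ORDER_NAMES
from .labels import LABELS, N_LABELS
from . import metrics as _metrics


class ClassifierConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; the head always has 8 sigmoid units."""

    stem_channels: int = 8
    widths: tuple[int, ...] = (16, 32)
    blocks_per_stage: int = 1  # each block is a VGG-style convolution pair
    kernel_size: int = 3
    stem_pool: bool = True  # 2x downsample right after the stem
    dropout: float = 0.0
    seed: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.widths)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    learning_rate: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 25
    patience: int = 5  # early stop on held-out loss
    test_fraction: float = 0.1


@dataclass
class TrainReport:
    """Everything needed to reproduce and audit one training run."""

    seed: int
    split_seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    epoch_train_loss: list[float] = field(default_factory=list)
    epoch_test_loss: list[float] = field(default_factory=list)
    epoch_test_macro_accuracy: list[float] = field(default_factory=list)
    epoch_test_mean_iou: list[float] = field(default_factory=list)
    untrainable_labels: list[str] = field(default_factory=list)
    final_test_macro_accuracy: float = float("nan")
    final_test_mean_iou: float = float("nan")
    best_epoch: int = -1

    def to_json(self) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2)


class MultilabelCNN:
    """The trained (or trainable) network plus its frame-layout metadata."""

    def __init__(self, config: NetworkConfig,
                 sensor_order: tuple[str, ...] = SENSOR_ORDER_NAMES) -> None:
        self.config = config
        self.sensor_order = tuple(sensor_order)
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        layers: list[nn.Layer] = [nn.Conv2D(FRAME_SHAPE[0], config.stem_channels, k, rng), nn.ReLU()]
        h, w = FRAME_SHAPE[1], FRAME_SHAPE[2]
        if config.stem_pool:
            layers.append(nn.AvgPool2())
            h, w = h // 2, w // 2
        c_prev = config.stem_channels
        for i, width in enumerate(config.widths):
            if i > 0:
                layers.append(nn.AvgPool2())
                h, w = h // 2, w // 2
            if h < k or w < k:
                raise ClassifierConfigError(
                    f"feature map {h}x{w} at stage {i} is smaller than the {k}x{k} kernel"
                )
            for _ in range(config.blocks_per_stage):
                layers.append(nn.ResidualBlock(c_prev, width, k, rng))
                c_prev = width
        layers.append(nn.GlobalAvgPool())
        if config.dropout > 0:
            layers.append(nn.Dropout(config.dropout, rng))
        layers.append(nn.Dense(c_prev, N_LABELS, rng))
        self.net = nn.Sequential(layers)

    # -- inference ---------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != FRAME_SHAPE:
            raise ValueError(f"input must be (batch,) + {FRAME_SHAPE}; got {x.shape}")
        return self.net.forward(x, train=train)

    def predict_scores(self, frames: np.ndarray, batch_size: int = 256) -> np.ndarray:
        frames = _as_frame_array(frames)
        out = np.empty((frames.shape[0], N_LABELS), dtype=np.float64)
        for lo in range(0, frames.shape[0], batch_size):
            out[lo : lo + batch_size] = nn.sigmoid(self.forward_logits(frames[lo : lo + batch_size]))
        return out

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.net.params


def build_network(config: NetworkConfig | None = None,
                  sensor_order: tuple[str, ...] = SENSOR_ORDER_NAMES) -> MultilabelCNN:
    """Construct a network with reproducible seeded initialization."""
    return MultilabelCNN(config or NetworkConfig(), sensor_order)


def _as_frame_array(frames) -> np.ndarray:
    if isinstance(frames, FrameDataset):
        return frames.frames.astype(np.float32)
    if isinstance(frames, EncodedFrame):
        return frames.values[None]
    if isinstance(frames, (list, tuple)) and frames and isinstance(frames[0], EncodedFrame):
        return np.stack([f.values for f in frames])
    arr = np.asarray(frames, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    return arr


def stratified_split(labels: np.ndarray, split_seed: int,
                     test_fraction: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test index split, stratified by full label combination.

    Each distinct 8-label combination contributes proportionally to the test
    set; the global test size is exactly round(test_fraction * n) (largest-
    remainder allocation across combinations).
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    n_test = int(round(test_fraction * n))
    rng = np.random.default_rng(split_seed)
    groups: dict[tuple, np.ndarray] = {}
    for key in map(tuple, np.unique(labels, axis=0)):
        idx = np.nonzero((labels == np.array(key)).all(axis=1))[0]
        groups[key] = rng.permutation(idx)
    quotas = {k: test_fraction * len(v) for k, v in groups.items()}
    take = {k: int(np.floor(q)) for k, q in quotas.items()}
    shortfall = n_test - sum(take.values())
    remainders = sorted(groups, key=lambda k: (-(quotas[k] - take[k]), k))
    for k in remainders[: max(shortfall, 0)]:
        if take[k] < len(groups[k]):
            take[k] += 1
    test_idx = np.concatenate([groups[k][: take[k]] for k in groups]) if groups else np.array([], int)
    # top up / trim if capped groups left the quota unmet
    if test_idx.size != n_test:
        all_idx = np.concatenate(list(groups.values()))
        rest = np.setdiff1d(all_idx, test_idx)
        if test_idx.size < n_test:
            test_idx = np.concatenate([test_idx, rest[: n_test - test_idx.size]])
        else:
            test_idx = test_idx[:n_test]
    test_idx = np.sort(test_idx)
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


def train(dataset: FrameDataset, config: NetworkConfig | None = None,
          split_seed: int = 0, train_config: TrainConfig | None = None
          ) -> tuple[MultilabelCNN, TrainReport]:
    """Fit the network on a stratified 90/10 split of the dataset.

    Deterministic given ``config.seed`` (initialization, batch order) and
    ``split_seed`` (the split).  Labels constant across the whole dataset, or
    single-class within the training split, are flagged untrainable with a
    warning and listed in the report; they stay in the loss, where a constant
    target simply drives the head bias toward that constant.
    """
    config = config or NetworkConfig()
    tc = train_config or TrainConfig()
    if len(dataset) < 100:
        raise ValueError(f"dataset must contain at least 100 windows; got {len(dataset)}")

    train_idx, test_idx = stratified_split(dataset.labels, split_seed, tc.test_fraction)
    x_train = dataset.frames[train_idx].astype(np.float32)
    y_train = dataset.labels[train_idx].astype(np.float32)
    x_test = dataset.frames[test_idx].astype(np.float32)
    y_test = dataset.labels[test_idx]

    label_mask = np.ones(N_LABELS, dtype=np.float32)
    untrainable = [name for j, name in enumerate(LABELS)
                   if y_train[:, j].min() == y_train[:, j].max()]
    if untrainable:
        warnings.warn(f"labels single-class in the training split (untrainable): {untrainable}")

    model = MultilabelCNN(config, dataset.sensor_order)
    opt = nn.Adam(model.net.params, model.net.grads, lr=tc.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    report = TrainReport(seed=config.seed, split_seed=split_seed,
                         train_indices=train_idx, test_indices=test_idx,
                         untrainable_labels=untrainable)
    best_loss = np.inf
    best_params = [p.copy() for p in model.net.params]
    stale = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for lo in range(0, len(order), tc.batch_size):
            sel = order[lo : lo + tc.batch_size]
            logits = model.forward_logits(x_train[sel], train=True)
            loss, dlogits = nn.bce_with_logits(logits, y_train[sel], label_mask)
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        report.epoch_train_loss.append(float(np.mean(losses)))

        test_logits = model.forward_logits(x_test)
        test_loss, _ = nn.bce_with_logits(test_logits, y_test.astype(np.float32), label_mask)
        pred = postprocess(nn.sigmoid(test_logits))
        acc = _metrics.accuracy(AnnotationTrack.from_labels(pred),
                                AnnotationTrack.from_labels(y_test))
        iou = _metrics.iou_score(AnnotationTrack.from_labels(pred),
                                 AnnotationTrack.from_labels(y_test))
        report.epoch_test_loss.append(test_loss)
        report.epoch_test_macro_accuracy.append(acc.macro)
        report.epoch_test_mean_iou.append(iou.mean)

        if test_loss < best_loss - 1e-6:
            best_loss = test_loss
            best_params = [p.copy() for p in model.net.params]
            report.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience:
                break

    for p, best in zip(model.net.params, best_params):
        p[...] = best
    e = report.best_epoch
    report.final_test_macro_accuracy = report.epoch_test_macro_accuracy[e]
    report.final_test_mean_iou = report.epoch_test_mean_iou[e]
    return model, report


def predict(model: MultilabelCNN, frames, sensor_order: tuple[str, ...] | None = None
            ) -> np.ndarray:
    """Per-frame label scores in [0, 1]; shape (n, 8).

    Refuses frames whose sensor-row order differs from the one the model was
    trained under.
    """
    if isinstance(frames, FrameDataset):
        sensor_order = frames.sensor_order
    if sensor_order is not None and tuple(sensor_order) != model.sensor_order:
        raise ValueError(
            f"frame sensor order {tuple(sensor_order)} does not match the model's "
            f"{model.sensor_order}"
        )
    return model.predict_scores(_as_frame_array(frames))


#: Posture columns ordered so that arg-max ties keep the later label
#: (LY < SI < ST < WA).
def postprocess(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Turn sigmoid scores into credible binary label vectors.

    Extremities are thresholded; among the four posture/walk scores exactly
    the arg-max is set (ties keep the highest-priority, i.e. latest, label in
    LY < SI < ST < WA order); a walking second forces both lower-extremity
    labels on.  Output always satisfies the credibility rules.
    """
    scores = np.asarray(scores, dtype=np.float64)
    squeeze = scores.ndim == 1
    if squeeze:
        scores = scores[None]
    if scores.shape[1] != N_LABELS:
        raise ValueError(f"scores must have {N_LABELS} columns; got {scores.shape}")
    out = np.zeros(scores.shape, dtype=np.uint8)
    out[:, 4:] = scores[:, 4:] >= threshold
    # arg-max keeping the later label on ties: arg-max over reversed columns
    posture = 3 - np.argmax(scores[:, 3::-1], axis=1)
    out[np.arange(len(out)), posture] = 1
    walking = out[:, 3] == 1
    out[walking, 6] = 1  # RL
    out[walking, 7] = 1  # LL
    return out[0] if squeeze else out


def save_model(model: MultilabelCNN, path: str | Path) -> None:
    """Checkpoint: architecture config, parameters and sensor-order metadata."""
    meta = {"config": asdict(model.config), "sensor_order": list(model.sensor_order),
            "labels_order": list(LABELS)}
    arrays = {f"param_{i}": p for i, p in enumerate(model.net.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> MultilabelCNN:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        cfg["widths"] = tuple(cfg["widths"])
        model = MultilabelCNN(NetworkConfig(**cfg), tuple(meta["sensor_order"]))
        for i, p in enumerate(model.net.params):
            p[...] = data[f"param_{i}"]
    return model
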