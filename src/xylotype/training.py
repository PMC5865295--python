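"""Two-phase transfer-learning schedule.

Phase 1 treats the convolutional backbone as a fixed feature extractor
(weights frozen) and trains only the head with SGD + momentum. Phase 2
unfreezes everything and fine-tunes with Adam, early-stopping when the
monitored split's patch accuracy stops improving and restoring the
best-epoch weights. Both phases minimize categorical cross-entropy.

Because frozen backbone weights cannot change, phase 1 computes every
patch's backbone feature map once and iterates epochs over the head only —
numerically identical to running the full network, but far cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from xylotype.nn.layers import softmax_cross_entropy
from xylotype.nn.network import Network
from xylotype.nn.optim import SGD, Adam

__all__ = [
    "TrainPhaseSpec",
    "TrainingHistory",
    "train_two_phase",
    "evaluate_epoch",
    "phase1_defaults",
    "phase2_defaults",
]


@dataclass(frozen=True)
class TrainPhaseSpec:
    """Hyperparameters of one training phase."""

    optimizer: str = "sgd"  # {"sgd", "adam"}
    learning_rate: float = 1e-4
    momentum: float = 0.9  # sgd only
    decay: float = 0.0  # adam only
    decay_mode: str = "lr"  # {"lr", "weight"}
    max_epochs: int = 30
    early_stop_patience: Optional[int] = None
    batch_size: int = 8
    freeze_backbone: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.early_stop_patience is not None and self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1 or None")

    def make_optimizer(self):
        if self.optimizer == "sgd":
            return SGD(self.learning_rate, momentum=self.momentum)
        return Adam(self.learning_rate, decay=self.decay, decay_mode=self.decay_mode)


def phase1_defaults(seed: int = 0, max_epochs: int = 30) -> TrainPhaseSpec:
    """Head-only phase: frozen backbone, SGD lr 1e-4, momentum 0.9, 30 epochs."""
    return TrainPhaseSpec(
        optimizer="sgd",
        learning_rate=1e-4,
        momentum=0.9,
        max_epochs=max_epochs,
        early_stop_patience=None,
        batch_size=8,
        freeze_backbone=True,
        seed=seed,
    )


def phase2_defaults(seed: int = 0, max_epochs: int = 100) -> TrainPhaseSpec:
    """Fine-tuning phase: Adam lr 1e-3, decay 5e-4, patience 10, 100 epochs."""
    return TrainPhaseSpec(
        optimizer="adam",
        learning_rate=1e-3,
        decay=5e-4,
        max_epochs=max_epochs,
        early_stop_patience=10,
        batch_size=8,
        freeze_backbone=False,
        seed=seed,
    )


@dataclass
class TrainingHistory:
    """Per-epoch records of both phases plus each phase's stopping epoch."""

    records: list[dict] = field(default_factory=list)
    stopping_epoch: dict[int, Optional[int]] = field(default_factory=dict)

    def append(self, phase, epoch, train_loss, train_acc, monitor_acc) -> None:
        self.records.append(
            dict(
                phase=phase,
                epoch=epoch,
                train_loss=train_loss,
                train_acc=train_acc,
                monitor_acc=monitor_acc,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["phase", "epoch", "train_loss", "train_acc", "monitor_acc"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def phase_records(self, phase: int) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[frame["phase"] == phase].reset_index(drop=True)

    def plot_curves(self, path: str | Path) -> None:
        """Accuracy-vs-epoch curves for both phases, one PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.to_frame()
        fig, ax = plt.subplots(figsize=(7, 4.5))
        offset = 0
        for phase in sorted(frame["phase"].unique()):
            sub = frame[frame["phase"] == phase]
            x = sub["epoch"] + offset
            ax.plot(x, sub["train_acc"], label=f"phase {phase} train")
            if sub["monitor_acc"].notna().any():
                ax.plot(x, sub["monitor_acc"], "--", label=f"phase {phase} monitor")
            offset += len(sub)
        ax.set_xlabel("epoch (phases concatenated)")
        ax.set_ylabel("patch accuracy")
        ax.set_ylim(0, 1.02)
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def evaluate_epoch(
    network: Network,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int = 64,
) -> tuple[float, float]:
    """Patch accuracy and mean cross-entropy on a patch set (eval mode).

    Accuracy counts patches whose argmax score equals the true label;
    ties resolve to the lowest class index.
    """
    if len(x) == 0:
        raise ValueError("patch set is empty")
    losses = []
    correct = 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = network.forward(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return correct / len(x), float(np.sum(losses) / len(x))


def _check_labels(y: np.ndarray, n_classes: int) -> None:
    present = set(np.unique(y).tolist())
    missing = sorted(set(range(n_classes)) - present)
    if missing:
        raise ValueError(
            f"training patches missing class indices {missing} "
            f"(model has {n_classes} outputs)"
        )


def _run_phase(
    network: Network,
    phase_idx: int,
    spec: TrainPhaseSpec,
    x: np.ndarray,
    y: np.ndarray,
    monitor: Optional[tuple[np.ndarray, np.ndarray]],
    history: TrainingHistory,
) -> None:
    spec.validate()
    if spec.max_epochs == 0:  # a zero-epoch phase leaves the model untouched
        history.stopping_epoch[phase_idx] = None
        return
    rng = np.random.default_rng(spec.seed)
    optimizer = spec.make_optimizer()
    network.set_backbone_trainable(not spec.freeze_backbone)

    features = None
    monitor_features = None
    if spec.freeze_backbone:
        # Frozen backbone => constant features; compute them once. The
        # batch-norm input distribution is fixed too, so one calibration
        # keeps evaluation-mode statistics exact for the whole phase.
        features = _batched_backbone(network, x)
        network.calibrate_batchnorm(features, from_features=True)
        if monitor is not None:
            monitor_features = _batched_backbone(network, monitor[0])

    best_acc = -np.inf
    best_epoch: Optional[int] = None
    best_state = None
    stop_epoch: Optional[int] = None

    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, len(order), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            yb = y[idx]
            if spec.freeze_backbone:
                logits = network.head_forward(features[idx], train=True, rng=rng)
            else:
                logits = network.forward(x[idx], train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at phase {phase_idx} epoch {epoch}: {loss}"
                )
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
            if spec.freeze_backbone:
                network.head_backward(dlogits)
            else:
                network.backward(dlogits)
            optimizer.step(network)

        train_loss = epoch_loss / len(x)
        train_acc = epoch_correct / len(x)

        monitor_acc = np.nan
        if monitor is not None:
            if spec.freeze_backbone:
                monitor_acc = _head_accuracy(network, monitor_features, monitor[1])
            else:
                # Fine-tuning shifts the feature distribution every step;
                # re-anchor BN statistics before the honest evaluation.
                network.calibrate_batchnorm(x)
                monitor_acc, _ = evaluate_epoch(network, monitor[0], monitor[1])
        history.append(phase_idx, epoch, train_loss, train_acc, monitor_acc)

        if monitor is not None and spec.early_stop_patience is not None:
            if monitor_acc > best_acc:  # strict improvement only
                best_acc = monitor_acc
                best_epoch = epoch
                best_state = network.get_weights()
            elif epoch - best_epoch >= spec.early_stop_patience:
                stop_epoch = epoch
                break

    if monitor is None and spec.max_epochs > 0 and not spec.freeze_backbone:
        network.calibrate_batchnorm(x)
    if best_state is not None:
        network.set_weights(best_state)
    if stop_epoch is not None:
        history.stopping_epoch[phase_idx] = stop_epoch
    else:
        history.stopping_epoch[phase_idx] = (
            spec.max_epochs - 1 if spec.max_epochs > 0 else None
        )


def _batched_backbone(network: Network, x: np.ndarray, batch_size: int = 64):
    outs = [
        network.backbone_forward(x[i : i + batch_size], train=False)
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def _head_accuracy(network: Network, features: np.ndarray, y: np.ndarray) -> float:
    correct = 0
    for i in range(0, len(features), 256):
        logits = network.head_forward(features[i : i + 256], train=False)
        correct += int((logits.argmax(axis=1) == y[i : i + 256]).sum())
    return correct / len(features)


def train_two_phase(
    network: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    monitor: Optional[tuple[np.ndarray, np.ndarray]] = None,
    phase1: Optional[TrainPhaseSpec] = None,
    phase2: Optional[TrainPhaseSpec] = None,
) -> TrainingHistory:
    """Run the two-phase schedule in place on ``network``.

    Parameters
    ----------
    x_train, y_train
        Training patches as float32 (N, 3, H, W) in [0, 1] and integer
        class indices.
    monitor
        Optional (x, y) patch set whose accuracy is tracked per epoch and
        drives phase-2 early stopping and best-weight restoration.
    phase1, phase2
        Phase hyperparameters; defaults follow the reference schedule.
    """
    if len(x_train) == 0:
        raise ValueError("training patch set is empty")
    phase1 = phase1 or phase1_defaults()
    phase2 = phase2 or phase2_defaults()
    n_classes = network.layers[-1][1].params["W"].shape[1]
    _check_labels(y_train, n_classes)

    history = TrainingHistory()
    initial_backbone = {
        f"{name}.{key}": layer.params[key].copy()
        for name, layer in network.layers[: network.n_backbone]
        for key in layer.params
    }
    _run_phase(network, 1, phase1, x_train, y_train, monitor, history)
    # Frozen-phase conservation: phase 1 must not have touched the backbone.
    for name, layer in network.layers[: network.n_backbone]:
        for key in layer.params:
            if not np.array_equal(layer.params[key], initial_backbone[f"{name}.{key}"]):
                raise RuntimeError(f"frozen backbone weight {name}.{key} changed")
    _run_phase(network, 2, phase2, x_train, y_train, monitor, history)
    return history
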