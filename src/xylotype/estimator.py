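"""Scikit-learn estimator facade over the patch classifier.

``WoodPatchCNN`` wraps architecture assembly and the two-phase training
schedule behind the familiar fit/predict/predict_proba contract, so the
classifier composes with sklearn pipelines and model selection. Inputs are
uint8 RGB patch arrays of shape (n_samples, height, width, 3); internally
they are scaled to [0, 1] and moved to channel-first layout.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from xylotype.arch import ArchitectureSpec, assemble
from xylotype.training import (
    TrainPhaseSpec,
    evaluate_epoch,
    train_two_phase,
)

__all__ = ["WoodPatchCNN", "preprocess_patches"]


def preprocess_patches(x: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8 -> float32 (N, 3, H, W) in [0, 1]."""
    x = np.asarray(x)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError(f"expected (n, height, width, 3) patches, got {x.shape}")
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32) / 255.0


class WoodPatchCNN(ClassifierMixin, BaseEstimator):
    """Truncated-backbone CNN classifier for transverse-surface patches.

    Parameters
    ----------
    backbone : {"mini", "vgg16_truncated"}
        Convolutional feature extractor. ``mini`` (3 convolutions of
        8/16/32 channels) is intended for desk-scale data; the truncated
        VGG16 (7 convolutions, 256 channels) is the reference.
    pooling : {"avg", "max"}
        Global pooling variant that turns the final feature map into a
        per-channel texture-energy vector.
    dropout : float
        Dropout rate between batch normalization and the softmax head.
    phase1_epochs, phase1_lr, phase1_momentum
        Head-only phase (frozen backbone, SGD with momentum).
    phase2_epochs, phase2_lr, phase2_decay, patience
        Fine-tuning phase (all weights, Adam with per-step lr decay,
        early stopping on the monitor split).
    decay_mode : {"lr", "weight"}
        Interpretation of ``phase2_decay``.
    monitor : {"val", "none"}
        ``val`` carves a stratified validation split of ``val_fraction``
        from the training patches to drive early stopping. An explicit
        monitor set passed to :meth:`fit` overrides this.
    pretrained : False or path
        Optional backbone checkpoint (``.npz``) to load before training.
    random_state : int
        Seeds weight initialization, the validation split, patch shuffling
        and dropout.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; columns of :meth:`predict_proba`.
    model_ : Network
        The trained network.
    history_ : TrainingHistory
        Per-epoch training record of both phases.
    summary_ : list of dict
        Layer-by-layer architecture summary.
    input_shape_ : tuple
        (height, width) of the training patches.
    """

    def __init__(
        self,
        backbone: str = "mini",
        pooling: str = "avg",
        dropout: float = 0.5,
        batch_size: int = 8,
        phase1_epochs: int = 30,
        phase1_lr: float = 1e-4,
        phase1_momentum: float = 0.9,
        phase2_epochs: int = 100,
        phase2_lr: float = 1e-3,
        phase2_decay: float = 5e-4,
        decay_mode: str = "lr",
        patience: Optional[int] = 10,
        monitor: str = "val",
        val_fraction: float = 0.15,
        pretrained: bool | str = False,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.pooling = pooling
        self.dropout = dropout
        self.batch_size = batch_size
        self.phase1_epochs = phase1_epochs
        self.phase1_lr = phase1_lr
        self.phase1_momentum = phase1_momentum
        self.phase2_epochs = phase2_epochs
        self.phase2_lr = phase2_lr
        self.phase2_decay = phase2_decay
        self.decay_mode = decay_mode
        self.patience = patience
        self.monitor = monitor
        self.val_fraction = val_fraction
        self.pretrained = pretrained
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, monitor_set: Optional[tuple] = None) -> "WoodPatchCNN":
        """Train on patches X (n, H, W, 3) with labels y.

        ``monitor_set`` is an optional (X_mon, y_mon) pair monitored per
        epoch instead of an internal validation split — use it to reproduce
        protocols that monitor the test split directly.
        """
        x = preprocess_patches(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.input_shape_ = x.shape[2:]

        spec = ArchitectureSpec(
            backbone=self.backbone,
            pooling_variant=(
                "global_average" if self.pooling == "avg" else "global_max"
            ),
            dropout_rate=self.dropout,
            n_classes=len(self.classes_),
            pretrained=self.pretrained,
        )
        network, self.summary_ = assemble(
            spec, self.input_shape_, seed=self.random_state
        )

        if monitor_set is not None:
            x_mon = preprocess_patches(monitor_set[0])
            y_mon = np.searchsorted(self.classes_, np.asarray(monitor_set[1]))
            mon = (x_mon, y_mon)
        elif self.monitor == "val":
            from sklearn.model_selection import train_test_split

            tr_idx, va_idx = train_test_split(
                np.arange(len(x)),
                test_size=self.val_fraction,
                random_state=self.random_state,
                stratify=y_idx,
            )
            mon = (x[va_idx], y_idx[va_idx])
            x, y_idx = x[tr_idx], y_idx[tr_idx]
        else:
            mon = None

        phase1 = TrainPhaseSpec(
            optimizer="sgd",
            learning_rate=self.phase1_lr,
            momentum=self.phase1_momentum,
            max_epochs=self.phase1_epochs,
            batch_size=self.batch_size,
            freeze_backbone=True,
            seed=self.random_state,
        )
        phase2 = TrainPhaseSpec(
            optimizer="adam",
            learning_rate=self.phase2_lr,
            decay=self.phase2_decay,
            decay_mode=self.decay_mode,
            max_epochs=self.phase2_epochs,
            early_stop_patience=self.patience,
            batch_size=self.batch_size,
            freeze_backbone=False,
            seed=self.random_state + 1,
        )
        self.history_ = train_two_phase(
            network, x, y_idx, monitor=mon, phase1=phase1, phase2=phase2
        )
        self.model_ = network
        return self

    # ------------------------------------------------------------ inference
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(preprocess_patches(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def evaluate(self, X, y) -> tuple[float, float]:
        """(patch accuracy, mean cross-entropy) on a labelled patch set."""
        check_is_fitted(self, "model_")
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        return evaluate_epoch(self.model_, preprocess_patches(X), y_idx)

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"X_types": ["3darray"], "non_deterministic": False}
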